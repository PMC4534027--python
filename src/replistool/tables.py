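"""Core tabular data model: count tables, sample metadata, taxonomy, compositions.

The pipeline's universal input is a samples × OTUs table of non-negative
integer read counts together with a metadata table mapping each sample to
its design cell (subject, collection medium, incubation time in days,
replicate number).  All tables are thin, validated wrappers around pandas
DataFrames; on-disk format is plain TSV.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Collection media evaluated by the study design.
MEDIA = ("none", "rnalater", "rnalater_kan", "rnalater_cipro")

#: Incubation times (days at room temperature before freezing).
TIMES = (0, 3, 7)

#: The four major phyla tracked individually; everything else maps to "other".
MAJOR_PHYLA = ("Firmicutes", "Bacteroidetes", "Actinobacteria", "Proteobacteria")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(ids, what: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))!r}")


@dataclass
class CountTable:
    """Samples × OTUs matrix of non-negative integer read counts.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by sample id, columns by OTU id, integer dtype.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "sample ids")
        _check_unique(df.columns, "OTU ids")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                bad = np.argwhere(np.mod(values, 1) != 0)[0]
                raise ValidationError(
                    f"non-integer count at sample {df.index[bad[0]]!r}, "
                    f"OTU {df.columns[bad[1]]!r}"
                )
            df = df.astype(np.int64)
            self.data = df
            values = df.to_numpy()
        if values.size and values.min() < 0:
            bad = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at sample {df.index[bad[0]]!r}, "
                f"OTU {df.columns[bad[1]]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def subset(self, sample_ids) -> "CountTable":
        return CountTable(self.data.loc[list(sample_ids)].copy())

    def __eq__(self, other) -> bool:
        return isinstance(other, CountTable) and self.data.equals(other.data)


@dataclass
class CompositionTable:
    """Samples × taxa matrix of relative abundances (rows sum to 1).

    Rows whose source counts summed to zero are left all-zero and listed in
    ``zero_total_samples``.
    """

    data: pd.DataFrame
    zero_total_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "taxon ids")
        values = self.data.to_numpy(dtype=float)
        if values.size:
            if values.min() < -1e-12 or values.max() > 1 + 1e-9:
                raise ValidationError("relative abundances must lie in [0, 1]")
            totals = values.sum(axis=1)
            zero = set(self.zero_total_samples)
            for sid, tot in zip(self.data.index, totals):
                if sid in zero:
                    if tot != 0:
                        raise ValidationError(
                            f"sample {sid!r} flagged zero-total but sums to {tot}"
                        )
                elif abs(tot - 1.0) > 1e-9:
                    raise ValidationError(
                        f"row for sample {sid!r} sums to {tot}, expected 1"
                    )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class SampleMetadata:
    """Per-sample design annotations: subject, medium, time, replicate."""

    data: pd.DataFrame

    REQUIRED = ("subject_id", "medium", "time_days", "replicate")

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        _check_unique(df.index, "sample ids")
        bad_media = set(df["medium"]) - set(MEDIA)
        if bad_media:
            raise ValidationError(f"unknown media: {sorted(bad_media)!r}")
        df["time_days"] = df["time_days"].astype(int)
        df["replicate"] = df["replicate"].astype(int)
        design = df[list(self.REQUIRED)]
        if design.duplicated().any():
            dup = design[design.duplicated()].iloc[0]
            raise ValidationError(
                f"duplicated design tuple {tuple(dup)} "
                "(subject, medium, time, replicate must be unique)"
            )
        # The reference design has no-media aliquots at time 0 only; other
        # designs are permitted with a warning.
        odd = df[(df["medium"] == "none") & (df["time_days"] != 0)]
        if len(odd):
            warnings.warn(
                f"{len(odd)} sample(s) with medium='none' at time > 0 "
                "(the reference design collects no-media aliquots at time 0 only)",
                UserWarning,
                stacklevel=2,
            )
            logger.warning("medium='none' at nonzero time for samples %s",
                           list(odd.index))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def stratum(self, medium=None, time_days=None, times=None) -> list[str]:
        """Sample ids in the requested (medium, time) stratum."""
        df = self.data
        mask = pd.Series(True, index=df.index)
        if medium is not None:
            mask &= df["medium"] == medium
        if time_days is not None:
            mask &= df["time_days"] == time_days
        if times is not None:
            mask &= df["time_days"].isin(list(times))
        return list(df.index[mask])

    def subjects(self) -> list[str]:
        return sorted(self.data["subject_id"].unique())


@dataclass
class TaxonomyMap:
    """OTU id → phylum assignment; unmapped OTUs resolve to "other"."""

    mapping: dict[str, str]

    def phylum(self, otu_id: str) -> str:
        return self.mapping.get(otu_id, "other")

    def phyla(self) -> list[str]:
        return sorted(set(self.mapping.values()) | {"other"})


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_count_table(path, orientation: str = "otus") -> CountTable:
    """Read a TSV count table.

    ``orientation='otus'`` (the common amplicon convention) expects OTUs in
    rows and samples in columns; ``'samples'`` expects the transpose.  The
    in-memory model is always samples × OTUs.
    """
    if orientation not in ("otus", "samples"):
        raise ValueError("orientation must be 'otus' or 'samples'")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    num = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        try:
            num[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValidationError(
                f"non-numeric count in column {col!r}, row {bad.index[0]!r}: "
                f"{bad.iloc[0]!r}"
            ) from exc
    if orientation == "otus":
        num = num.T
    num.index.name = "sample_id"
    return CountTable(num)


def write_count_table(table: CountTable, path, orientation: str = "otus") -> None:
    df = table.data
    if orientation == "otus":
        df = df.T
        df.index.name = "otu_id"
    df.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    if "sample_id" not in df.columns:
        raise ValidationError("metadata must have a sample_id column")
    df = df.set_index("sample_id")
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.data.to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy(path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", header=None, names=["otu_id", "phylum"],
                     dtype=str, comment="#")
    _check_unique(df["otu_id"], "OTU ids in taxonomy map")
    return TaxonomyMap(dict(zip(df["otu_id"], df["phylum"])))


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    with open(path, "w") as fh:
        for otu, phylum in tax.mapping.items():
            fh.write(f"{otu}\t{phylum}\n")


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def relative_abundance(table: CountTable) -> CompositionTable:
    """Convert counts to per-sample relative abundances.

    Zero-total rows cannot be normalized; they are left all-zero and flagged
    in ``zero_total_samples``.
    """
    counts = table.data.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    zero = totals == 0
    safe = np.where(zero, 1.0, totals)
    comp = counts / safe[:, None]
    flagged = [sid for sid, z in zip(table.sample_ids, zero) if z]
    if flagged:
        logger.warning("zero-total samples left unnormalized: %s", flagged)
    df = pd.DataFrame(comp, index=table.data.index, columns=table.data.columns)
    return CompositionTable(df, zero_total_samples=flagged)


def aggregate_by_phylum(comp: CompositionTable, tax: TaxonomyMap) -> CompositionTable:
    """Collapse OTU columns to phylum columns, conserving per-sample totals."""
    phyla = [tax.phylum(o) for o in comp.data.columns]
    agg = comp.data.T.groupby(pd.Index(phyla, name="phylum")).sum().T
    return CompositionTable(agg, zero_total_samples=list(comp.zero_total_samples))
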