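"""End-to-end reproducibility analysis of a replicated microbiome study.

``ReproducibilityStudy`` is the model object: construct it from a count
table, sample metadata, a rooted tree and a taxonomy map (or from files),
then call :meth:`fit` to obtain a :class:`StudyResults` with

* technical reproducibility at time 0 — per collection medium, the ICC
  (with permutation p-value) of 14 microbiota metrics across triplicate
  samples grouped by subject: 4 major-phylum relative abundances, 4
  rarefied alpha-diversity metrics (PD whole tree, Chao1, observed
  species, Shannon) and the top 3 principal coordinates of the unweighted
  and weighted UniFrac distance matrices, plus the UniFrac distance-based
  R² by subject;
* temporal stability — for each medium and delay (day 3 vs 0, day 7 vs 0),
  the ICC of per-subject replicate averages and the UniFrac R²;
* media comparison — paired t-tests of per-subject phylum abundances,
  no-media vs each medium at time 0;
* the abundance–reproducibility trend — OLS of per-taxon ICC on log mean
  relative abundance above a 0.1% floor.

Principal coordinates are computed once over all samples jointly and the
per-stratum slices of those global axes are scored, so every stratum is
measured on shared axes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import tables
from .alpha import alpha_with_rarefaction
from .beta import PCoAResult, pcoa, unifrac_matrix, variance_explained_r2
from .icc import (OneWayICCResults, abundance_icc_trend, icc_oneway,
                  phylum_media_ttest, TrendResult)
from .tables import (CountTable, SampleMetadata, TaxonomyMap, MAJOR_PHYLA,
                     aggregate_by_phylum, relative_abundance)
from .tree import PhyloTree

logger = logging.getLogger(__name__)

ALPHA_LABELS = {"pd": "PD_WT", "chao1": "Chao1",
                "observed_species": "Observed_species", "shannon": "Shannon"}

#: Table-1 row order: 4 phyla, 4 alpha metrics, 6 PCoA scores.
METRIC_ROWS = (
    "Actinobacteria", "Bacteroidetes", "Firmicutes", "Proteobacteria",
    "PD_WT", "Chao1", "Observed_species", "Shannon",
    "Unweighted.PCoA1", "Unweighted.PCoA2", "Unweighted.PCoA3",
    "Weighted.PCoA1", "Weighted.PCoA2", "Weighted.PCoA3",
)
R2_ROWS = ("Unweighted UniFrac", "Weighted UniFrac")

STUDY_MEDIA = ("none", "rnalater", "rnalater_kan", "rnalater_cipro")
LATER_TIMES = (3, 7)


@dataclass
class RunConfig:
    """Serializable run configuration mirroring the CLI flags."""

    counts_path: str = ""
    metadata_path: str = ""
    tree_path: str = ""
    taxonomy_path: str = ""
    orientation: str = "otus"
    depth: int = 5000
    draws: int = 20
    n_perm: int = 999
    seed: int = 0
    trend_floor: float = 0.001
    trend_medium: str = "rnalater"
    output_dir: str = "."

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        casts = {"int": int, "float": float, "str": str}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, val = line.split("=", 1)
            key = key.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[key] = casts.get(types[key], str)(val.strip())
        return cls(**kwargs)


def _stream(seed: int, *labels) -> list[int]:
    out = [int(seed) & 0x7FFFFFFF]
    out.extend(zlib.crc32(str(lbl).encode()) for lbl in labels)
    return out


def _grouped_by_subject(meta: SampleMetadata, values: pd.Series, sample_ids):
    """(subject, replicate values) pairs, dropping NaN values."""
    sub = values.loc[sample_ids].dropna()
    subjects = meta.data.loc[sub.index, "subject_id"]
    return [(subj, list(vals)) for subj, vals in sub.groupby(subjects)]


def _icc_or_none(grouped, min_subjects: int = 2):
    usable = [(g, v) for g, v in grouped if len(v) >= 2]
    if len(usable) < min_subjects:
        return None
    try:
        return icc_oneway(grouped)
    except ValueError:
        return None


class ReproducibilityStudy:
    """Model object for a replicated-design microbiome reproducibility study."""

    def __init__(self, counts: CountTable, metadata: SampleMetadata,
                 tree: PhyloTree, taxonomy: TaxonomyMap,
                 config: RunConfig | None = None):
        self.counts = counts
        self.metadata = metadata
        self.tree = tree
        self.taxonomy = taxonomy
        self.config = config or RunConfig()
        extra = set(counts.sample_ids) - set(metadata.sample_ids)
        if extra:
            raise ValueError(f"samples missing from metadata: {sorted(extra)[:5]}")

    @classmethod
    def from_files(cls, config: RunConfig) -> "ReproducibilityStudy":
        counts = tables.read_count_table(config.counts_path,
                                         orientation=config.orientation)
        meta = tables.read_metadata(config.metadata_path)
        tree = PhyloTree.read(config.tree_path)
        tax = tables.read_taxonomy(config.taxonomy_path)
        return cls(counts, meta, tree, tax, config=config)

    # ------------------------------------------------------------------
    # per-sample metric computation
    # ------------------------------------------------------------------

    def _metric_table(self, seed: int):
        cfg = self.config
        comp = relative_abundance(self.counts)
        phyla = aggregate_by_phylum(comp, self.taxonomy).data
        cols = {}
        for phylum in MAJOR_PHYLA:
            cols[phylum] = phyla.get(phylum, pd.Series(0.0, index=phyla.index))

        alpha = alpha_with_rarefaction(
            self.counts, metrics=("pd", "chao1", "observed_species", "shannon"),
            depth=cfg.depth, draws=cfg.draws, seed=seed, tree=self.tree)
        for key, label in ALPHA_LABELS.items():
            cols[label] = alpha.values[key]

        dms, ordinations = {}, {}
        for kind, label in (("unweighted", "Unweighted"), ("weighted", "Weighted")):
            dm = unifrac_matrix(self.counts, self.tree, kind=kind,
                                depth=cfg.depth, seed=seed)
            ord_res = pcoa(dm, n_axes=3)
            dms[kind] = dm
            ordinations[kind] = ord_res
            for j, axis in enumerate(ord_res.coordinates.columns, start=1):
                cols[f"{label}.PCoA{j}"] = ord_res.coordinates[axis]

        metric_values = pd.DataFrame(cols).reindex(self.counts.data.index)
        metric_values = metric_values[[c for c in METRIC_ROWS
                                       if c in metric_values.columns]]
        return metric_values, comp, phyla, dms, ordinations, alpha

    # ------------------------------------------------------------------
    # fit
    # ------------------------------------------------------------------

    def fit(self, seed: int | None = None) -> "StudyResults":
        cfg = self.config
        seed = cfg.seed if seed is None else int(seed)
        meta = self.metadata
        (metric_values, comp, phyla, dms, ordinations,
         alpha) = self._metric_table(seed)

        media_present = [m for m in STUDY_MEDIA
                         if m in set(meta.data["medium"])]

        time0_rows = self._time0_report(metric_values, dms, media_present, seed)
        temporal_rows = self._temporal_report(metric_values, dms,
                                              media_present, seed)
        media_cmp = self._media_comparison(phyla)
        trend, trend_taxa = self._abundance_trend(comp, seed)

        return StudyResults(
            model=self,
            metric_values=metric_values,
            time0=pd.DataFrame(time0_rows),
            temporal=pd.DataFrame(temporal_rows),
            media_comparison=media_cmp,
            trend=trend,
            trend_taxa=trend_taxa,
            ordinations=ordinations,
            phylum_abundances=phyla,
            n_excluded=int(alpha.excluded.sum()),
            seed=seed,
        )

    def _time0_report(self, metric_values, dms, media_present, seed):
        cfg, meta = self.config, self.metadata
        rows = []
        for medium in media_present:
            sids = meta.stratum(medium=medium, time_days=0)
            if not sids:
                continue
            for metric in metric_values.columns:
                grouped = _grouped_by_subject(meta, metric_values[metric], sids)
                res = _icc_or_none(grouped)
                if res is None:
                    logger.warning("time-0 %s/%s: too few replicates, cell NA",
                                   medium, metric)
                    rows.append(dict(metric=metric, medium=medium, time_days=0,
                                     icc=np.nan, icc_raw=np.nan, p_perm=np.nan,
                                     n_subjects=0))
                    continue
                p = res.permutation_test(
                    n_perm=cfg.n_perm,
                    seed=_stream(seed, "perm0", medium, metric))
                rows.append(dict(metric=metric, medium=medium, time_days=0,
                                 icc=res.icc_report, icc_raw=res.icc, p_perm=p,
                                 n_subjects=res.n_groups))
            for kind, label in (("unweighted", "Unweighted UniFrac"),
                                ("weighted", "Weighted UniFrac")):
                dm = dms[kind]
                ids = [s for s in sids if s in set(dm.ids)]
                subj = {s: meta.data.loc[s, "subject_id"] for s in ids}
                if len(set(subj.values())) < 2:
                    continue
                r2 = variance_explained_r2(dm.filter(ids), subj,
                                           grouping_name="subject")
                rows.append(dict(metric=label, medium=medium, time_days=0,
                                 icc=r2.r2, icc_raw=r2.r2, p_perm=np.nan,
                                 n_subjects=r2.n_groups))
        return rows

    def _temporal_report(self, metric_values, dms, media_present, seed):
        meta = self.metadata
        rows = []
        for medium in media_present:
            if medium == "none":
                continue
            for t in LATER_TIMES:
                sids_t = meta.stratum(medium=medium, time_days=t)
                sids_0 = meta.stratum(medium=medium, time_days=0)
                if not sids_t or not sids_0:
                    continue
                for metric in metric_values.columns:
                    avg_t = self._subject_averages(metric_values[metric], sids_t)
                    avg_0 = self._subject_averages(metric_values[metric], sids_0)
                    common = sorted(set(avg_t) & set(avg_0))
                    if len(common) < 2:
                        rows.append(dict(metric=metric, medium=medium,
                                         time_days=t, icc=np.nan,
                                         icc_raw=np.nan, n_subjects=0))
                        continue
                    grouped = [(g, [avg_t[g], avg_0[g]]) for g in common]
                    res = icc_oneway(grouped)
                    rows.append(dict(metric=metric, medium=medium, time_days=t,
                                     icc=res.icc_report, icc_raw=res.icc,
                                     n_subjects=res.n_groups))
                for kind, label in (("unweighted", "Unweighted UniFrac"),
                                    ("weighted", "Weighted UniFrac")):
                    dm = dms[kind]
                    ids = [s for s in sids_t + sids_0 if s in set(dm.ids)]
                    subj = {s: meta.data.loc[s, "subject_id"] for s in ids}
                    if len(set(subj.values())) < 2:
                        continue
                    r2 = variance_explained_r2(dm.filter(ids), subj,
                                               grouping_name="subject")
                    rows.append(dict(metric=label, medium=medium, time_days=t,
                                     icc=r2.r2, icc_raw=r2.r2,
                                     n_subjects=r2.n_groups))
        return rows

    def _subject_averages(self, values: pd.Series, sample_ids) -> dict[str, float]:
        sub = values.loc[sample_ids].dropna()
        subjects = self.metadata.data.loc[sub.index, "subject_id"]
        return sub.groupby(subjects).mean().to_dict()

    def _media_comparison(self, phyla: pd.DataFrame) -> pd.DataFrame:
        meta = self.metadata
        media = [m for m in STUDY_MEDIA if m != "none"
                 and m in set(meta.data["medium"])]
        none_ids = meta.stratum(medium="none", time_days=0)
        rows = []
        for phylum in MAJOR_PHYLA:
            vals = phyla.get(phylum, pd.Series(0.0, index=phyla.index))
            none_avg = self._subject_averages(vals, none_ids) if none_ids else {}
            for medium in media:
                med_ids = meta.stratum(medium=medium, time_days=0)
                med_avg = self._subject_averages(vals, med_ids)
                common = sorted(set(none_avg) & set(med_avg))
                t = p = np.nan
                if len(common) >= 3:
                    t, p = phylum_media_ttest([none_avg[s] for s in common],
                                              [med_avg[s] for s in common])
                rows.append(dict(
                    phylum=phylum, medium=medium, t=t, p=p,
                    n_subjects=len(common),
                    median_no_media=float(np.median(list(none_avg.values())))
                    if none_avg else np.nan,
                    median_medium=float(np.median(list(med_avg.values())))
                    if med_avg else np.nan,
                ))
        return pd.DataFrame(rows)

    def _abundance_trend(self, comp, seed):
        cfg, meta = self.config, self.metadata
        sids = meta.stratum(medium=cfg.trend_medium, time_days=0)
        if not sids:
            return None, pd.DataFrame()
        sub = comp.data.loc[sids]
        mean_ab = sub.mean(axis=0)
        median_ab = sub.median(axis=0)
        iccs, means = {}, {}
        for otu in sub.columns:
            if median_ab[otu] < cfg.trend_floor:
                continue
            grouped = _grouped_by_subject(meta, sub[otu], sids)
            res = _icc_or_none(grouped)
            if res is None:
                continue
            iccs[otu] = res.icc_report
            means[otu] = float(mean_ab[otu])
        if len(iccs) < 3:
            logger.warning("abundance trend skipped: only %d taxa above floor",
                           len(iccs))
            return None, pd.DataFrame()
        trend = abundance_icc_trend(iccs, means, floor=0.0)
        taxa = pd.DataFrame({
            "mean_abundance": pd.Series(means),
            "median_abundance": median_ab.loc[list(means)],
            "icc": pd.Series(iccs),
        }).sort_values("mean_abundance", ascending=False)
        taxa.index.name = "taxon"
        return trend, taxa


@dataclass
class StudyResults:
    """Fitted study: Table-1/Table-2-shaped reports and diagnostics."""

    model: ReproducibilityStudy
    metric_values: pd.DataFrame
    time0: pd.DataFrame
    temporal: pd.DataFrame
    media_comparison: pd.DataFrame
    trend: TrendResult | None
    trend_taxa: pd.DataFrame
    ordinations: dict[str, PCoAResult]
    phylum_abundances: pd.DataFrame
    n_excluded: int
    seed: int

    # -- pivoted report tables -----------------------------------------

    def table1(self, value: str = "icc") -> pd.DataFrame:
        """Technical reproducibility by medium at each time point."""
        df = self.time0.copy()
        if len(self.temporal):
            later = self.temporal.copy()
            later["medium_time"] = later["medium"] + " (day " + \
                later["time_days"].astype(str) + " vs 0)"
        piv = df.pivot(index="metric", columns="medium", values=value)
        order = [m for m in STUDY_MEDIA if m in piv.columns]
        rows = [r for r in list(METRIC_ROWS) + list(R2_ROWS) if r in piv.index]
        return piv.loc[rows, order]

    def table2(self, value: str = "icc") -> pd.DataFrame:
        """Temporal stability (day 3 vs 0 and day 7 vs 0) by medium."""
        if not len(self.temporal):
            return pd.DataFrame()
        df = self.temporal.copy()
        df["column"] = df["time_days"].map({3: "day3_vs_0", 7: "day7_vs_0"}) \
            + ":" + df["medium"]
        piv = df.pivot(index="metric", columns="column", values=value)
        rows = [r for r in list(METRIC_ROWS) + list(R2_ROWS) if r in piv.index]
        cols = sorted(piv.columns)
        return piv.loc[rows, cols]

    # -- presentation ---------------------------------------------------

    def summary(self) -> str:
        lines = ["Replicated-study reproducibility analysis",
                 "=" * 60,
                 f"samples: {len(self.metric_values)}   "
                 f"subjects: {len(self.model.metadata.subjects())}   "
                 f"excluded (under depth): {self.n_excluded}",
                 "",
                 "Technical reproducibility at time 0 (ICC / UniFrac R2):"]
        lines.append(self.table1().round(3).to_string())
        if len(self.temporal):
            lines += ["", "Temporal stability (ICC / UniFrac R2):",
                      self.table2().round(3).to_string()]
        if len(self.media_comparison):
            lines += ["", "No-media vs media, paired t-tests on phylum "
                          "relative abundance:",
                      self.media_comparison.round(4).to_string(index=False)]
        if self.trend is not None:
            lines += ["", f"Abundance-reproducibility trend "
                          f"({self.model.config.trend_medium}, time 0): "
                          f"slope={self.trend.slope:.4f} per ln-unit, "
                          f"p={self.trend.p_value:.2e}, "
                          f"n_taxa={self.trend.n_taxa}"]
        return "\n".join(lines)

    def to_tsv(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.time0.to_csv(out / "time0_reproducibility.tsv", sep="\t",
                          index=False)
        self.temporal.to_csv(out / "temporal_stability.tsv", sep="\t",
                             index=False)
        self.media_comparison.to_csv(out / "media_comparison.tsv", sep="\t",
                                     index=False)
        self.metric_values.to_csv(out / "metric_values.tsv", sep="\t")
        if len(self.trend_taxa):
            self.trend_taxa.to_csv(out / "abundance_trend_taxa.tsv", sep="\t")
        blob = {
            "seed": self.seed,
            "time0": self.time0.to_dict(orient="records"),
            "temporal": self.temporal.to_dict(orient="records"),
            "media_comparison": self.media_comparison.to_dict(orient="records"),
            "trend": dataclasses.asdict(self.trend) if self.trend else None,
            "n_excluded": self.n_excluded,
        }
        (out / "report.json").write_text(json.dumps(blob, indent=2,
                                                    default=float))


# ---------------------------------------------------------------------------
# functional entry points
# ---------------------------------------------------------------------------

def run_time0_reproducibility(config: RunConfig) -> StudyResults:
    """Fit the study from files and return the full results (Table-1 view)."""
    return ReproducibilityStudy.from_files(config).fit()


def run_temporal_stability(config: RunConfig) -> StudyResults:
    """Fit the study from files; Table-2 view lives in results.table2()."""
    return ReproducibilityStudy.from_files(config).fit()


def run_media_comparison(config: RunConfig) -> pd.DataFrame:
    return ReproducibilityStudy.from_files(config).fit().media_comparison


def run_abundance_trend(config: RunConfig):
    res = ReproducibilityStudy.from_files(config).fit()
    return res.trend, res.trend_taxa
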