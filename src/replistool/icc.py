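"""Variance-component intraclass correlation and permutation inference.

The reproducibility of a microbiome measurement across technical replicates
is summarized by the one-way random-effects intraclass correlation

    ICC = sigma_b^2 / (sigma_b^2 + sigma_e^2),

where sigma_b^2 is the between-subject variance and sigma_e^2 the
within-subject (replicate) variance.  Estimation uses the classical
ANOVA-moment estimator (Searle): with between- and within-group mean
squares MSB and MSW and effective group size k,

    ICC_hat = (MSB - MSW) / (MSB + (k - 1) MSW),
    sigma_e2_hat = MSW,   sigma_b2_hat = max(0, (MSB - MSW) / k),

and for unbalanced designs k = (N - sum n_g^2 / N) / (G - 1).  The raw
(possibly negative) ICC estimate is retained; a [0, 1]-clamped value is
reported alongside.

Inference is by permutation: the null "the measures are random across
technical replicates" (ICC = 0) is simulated by shuffling all values across
groups, preserving group sizes, with the add-one-smoothed p-value
(1 + #{perm >= obs}) / (n_perm + 1).

The module is organized statsmodels-style: ``OneWayICC`` is the model,
``fit()`` returns ``OneWayICCResults`` carrying estimates, diagnostics, a
``summary()`` table and the permutation tests.  Thin functional wrappers
(``icc_oneway`` etc.) cover scripting use.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

logger = logging.getLogger(__name__)

#: list of (group_id, replicate values) pairs — one group per subject.
GroupedValues = Sequence[tuple[str, Sequence[float]]]


# ---------------------------------------------------------------------------
# core estimator
# ---------------------------------------------------------------------------

def _anova_components(values: np.ndarray, indicator: np.ndarray,
                      sizes: np.ndarray):
    """One-way ANOVA mean squares for values laid out along the last axis.

    ``indicator`` is the N × G group membership matrix, ``sizes`` the group
    sizes.  Works for any leading batch shape (used to vectorize
    permutations).
    """
    n = values.shape[-1]
    g = len(sizes)
    group_sums = values @ indicator                       # (..., G)
    grand = values.sum(axis=-1, keepdims=True)
    ssb = (group_sums ** 2 / sizes).sum(axis=-1) - (grand[..., 0] ** 2) / n
    sst = (values ** 2).sum(axis=-1) - (grand[..., 0] ** 2) / n
    ssw = sst - ssb
    msb = ssb / (g - 1)
    msw = ssw / (n - g)
    return msb, msw, sst


def _icc_from_ms(msb, msw, k_eff):
    denom = msb + (k_eff - 1.0) * msw
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(denom > 0, (msb - msw) / np.where(denom > 0, denom, 1.0), 1.0)
    return icc


class OneWayICC:
    """One-way random-effects model for grouped replicate measurements.

    Parameters
    ----------
    values : array-like
        The measurements, one per observation.
    groups : array-like
        Group (subject) label per observation; groups need not be balanced.
    """

    def __init__(self, values, groups):
        values = np.asarray(values, dtype=float)
        groups = np.asarray(groups)
        if values.ndim != 1 or values.shape != groups.shape:
            raise ValueError("values and groups must be equal-length 1-D arrays")
        if np.isnan(values).any():
            keep = ~np.isnan(values)
            logger.warning("dropping %d NaN observation(s)", (~keep).sum())
            values, groups = values[keep], groups[keep]
        labels, codes = np.unique(groups, return_inverse=True)
        sizes = np.bincount(codes)
        if len(labels) < 2:
            raise ValueError("need at least 2 groups")
        if len(values) - len(labels) < 1:
            raise ValueError("need at least 1 within-group degree of freedom "
                             "(some group must have >= 2 replicates)")
        order = np.argsort(codes, kind="stable")
        self.values = values[order]
        self.codes = codes[order]
        self.group_labels = labels
        self.sizes = sizes
        self.nobs = len(values)
        self.indicator = np.zeros((self.nobs, len(labels)))
        self.indicator[np.arange(self.nobs), self.codes] = 1.0

    @classmethod
    def from_groups(cls, grouped: GroupedValues) -> "OneWayICC":
        values, groups = [], []
        for gid, vals in grouped:
            vals = list(vals)
            if len(vals) == 0:
                raise ValueError(f"group {gid!r} has no values")
            values.extend(float(v) for v in vals)
            groups.extend([gid] * len(vals))
        return cls(values, groups)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, value_col: str,
                       group_col: str) -> "OneWayICC":
        return cls(data[value_col].to_numpy(dtype=float),
                   data[group_col].to_numpy())

    @property
    def k_effective(self) -> float:
        n, g = self.nobs, len(self.sizes)
        return (n - (self.sizes ** 2).sum() / n) / (g - 1)

    def fit(self) -> "OneWayICCResults":
        msb, msw, sst = _anova_components(self.values, self.indicator, self.sizes)
        k = self.k_effective
        degenerate = sst <= 1e-14 * max(1.0, float(np.abs(self.values).max()) ** 2)
        if degenerate:
            icc = 1.0
            msb = msw = 0.0
        else:
            icc = float(_icc_from_ms(msb, msw, k))
        sigma_e2 = float(msw)
        sigma_b2 = max(0.0, float((msb - msw) / k))
        return OneWayICCResults(
            model=self, icc=float(icc), sigma_b2_hat=sigma_b2,
            sigma_e2_hat=sigma_e2, msb=float(msb), msw=float(msw),
            n_groups=len(self.sizes), k_effective=float(k),
            degenerate=bool(degenerate),
        )


@dataclass
class OneWayICCResults:
    """Fitted one-way ICC: point estimates, variance components, inference.

    ``icc`` is the raw ANOVA-moment estimate (may fall below 0 or above 1
    in small samples); ``icc_report`` clamps it to [0, 1] for presentation.
    """

    model: OneWayICC
    icc: float
    sigma_b2_hat: float
    sigma_e2_hat: float
    msb: float
    msw: float
    n_groups: int
    k_effective: float
    degenerate: bool = False
    p_perm: float | None = None
    n_perm: int = 0
    _perm_cache: dict = field(default_factory=dict, repr=False)

    @property
    def icc_report(self) -> float:
        return float(min(1.0, max(0.0, self.icc)))

    @property
    def nobs(self) -> int:
        return self.model.nobs

    def permutation_test(self, n_perm: int = 999, seed: int = 0) -> float:
        """Permutation p-value for the null ICC = 0.

        All values are shuffled across groups (group sizes preserved);
        p = (1 + #{perm ICC >= observed ICC}) / (n_perm + 1).
        """
        if n_perm < 99:
            raise ValueError("n_perm must be at least 99")
        key = (n_perm, tuple(seed) if isinstance(seed, (list, tuple)) else seed)
        if key in self._perm_cache:
            return self._perm_cache[key]
        rng = np.random.default_rng(seed)
        m = self.model
        perms = rng.permuted(np.broadcast_to(m.values, (n_perm, m.nobs)).copy(),
                             axis=1)
        msb, msw, _ = _anova_components(perms, m.indicator, m.sizes)
        perm_icc = _icc_from_ms(msb, msw, m.k_effective)
        p = float((1 + np.sum(perm_icc >= self.icc - 1e-12)) / (n_perm + 1))
        self.p_perm, self.n_perm = p, n_perm
        self._perm_cache[key] = p
        return p

    def summary(self) -> str:
        rows = [
            ("ICC (raw)", f"{self.icc:.4f}"),
            ("ICC (reported)", f"{self.icc_report:.4f}"),
            ("sigma_b^2", f"{self.sigma_b2_hat:.4g}"),
            ("sigma_e^2", f"{self.sigma_e2_hat:.4g}"),
            ("MSB", f"{self.msb:.4g}"),
            ("MSW", f"{self.msw:.4g}"),
            ("groups", f"{self.n_groups}"),
            ("observations", f"{self.nobs}"),
            ("k (effective)", f"{self.k_effective:.4g}"),
        ]
        if self.p_perm is not None:
            rows.append(("P (permutation)", f"{self.p_perm:.4g} "
                                            f"[{self.n_perm} perms]"))
        if self.degenerate:
            rows.append(("note", "degenerate: all values identical"))
        width = max(len(r[0]) for r in rows)
        lines = ["One-way random-effects ICC",
                 "=" * (width + 14)]
        lines += [f"{name:<{width}}  {val}" for name, val in rows]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def icc_oneway(data: GroupedValues) -> OneWayICCResults:
    """ANOVA-moment ICC for a list of (group, replicate values) pairs."""
    return OneWayICC.from_groups(data).fit()


def icc_permutation_pvalue(data: GroupedValues, n_perm: int = 999,
                           seed: int = 0) -> float:
    """Permutation p-value for ICC = 0 on grouped replicate values."""
    return icc_oneway(data).permutation_test(n_perm=n_perm, seed=seed)


def icc_difference_test(data_a: GroupedValues, data_b: GroupedValues,
                        n_perm: int = 999, seed: int = 0) -> float:
    """Permutation test of equal ICCs between two paired conditions.

    The statistic is |ICC_a - ICC_b|.  Under the null the condition labels
    are exchangeable within subject, so each permutation swaps, per subject
    independently with probability 1/2, the subject's full replicate set
    between the two conditions.  Subjects present in only one condition are
    excluded with a warning.
    """
    map_a = {g: np.asarray(v, dtype=float) for g, v in data_a}
    map_b = {g: np.asarray(v, dtype=float) for g, v in data_b}
    common = sorted(set(map_a) & set(map_b), key=str)
    dropped = (set(map_a) | set(map_b)) - set(common)
    if dropped:
        warnings.warn(f"subjects present in one condition only, excluded: "
                      f"{sorted(dropped, key=str)}", UserWarning, stacklevel=2)
    if len(common) < 2:
        raise ValueError("need at least 2 subjects present in both conditions")
    a_sets = [map_a[g] for g in common]
    b_sets = [map_b[g] for g in common]

    def _stat(a_list, b_list) -> float:
        res_a = icc_oneway(list(zip(common, a_list)))
        res_b = icc_oneway(list(zip(common, b_list)))
        return abs(res_a.icc - res_b.icc)

    observed = _stat(a_sets, b_sets)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        flips = rng.random(len(common)) < 0.5
        pa = [b if f else a for a, b, f in zip(a_sets, b_sets, flips)]
        pb = [a if f else b for a, b, f in zip(a_sets, b_sets, flips)]
        if _stat(pa, pb) >= observed - 1e-12:
            count += 1
    return float((1 + count) / (n_perm + 1))


def temporal_icc(values_t: Mapping[str, float],
                 values_0: Mapping[str, float]) -> OneWayICCResults:
    """Temporal-stability ICC between two time points.

    Each subject contributes a 2-value group — its replicate-averaged
    measurement at the later time and at time 0 — and the one-way ICC is
    computed over these pairs (k = 2).  A value near 1 means subjects keep
    their relative ordering over the delay.
    """
    common = sorted(set(values_t) & set(values_0), key=str)
    dropped = (set(values_t) | set(values_0)) - set(common)
    if dropped:
        warnings.warn(f"subjects missing at one time point, excluded: "
                      f"{sorted(dropped, key=str)}", UserWarning, stacklevel=2)
    if len(common) < 2:
        raise ValueError("need at least 2 subjects present at both times")
    grouped = [(g, [float(values_t[g]), float(values_0[g])]) for g in common]
    return icc_oneway(grouped)


def phylum_media_ttest(values_no_media, values_media) -> tuple[float, float]:
    """Paired two-sided t-test of per-subject phylum abundances.

    ``values_no_media`` and ``values_media`` are subject-aligned sequences
    of replicate-averaged relative abundances.  No multiplicity correction
    is applied.  With zero-variance differences the test degenerates: a
    zero mean difference reports (0.0, 1.0); a nonzero constant difference
    reports (inf-signed t, 0.0).
    """
    a = np.asarray(values_no_media, dtype=float)
    b = np.asarray(values_media, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be equal-length 1-D")
    if len(a) < 3:
        raise ValueError("need at least 3 paired subjects")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return 0.0, 1.0
        return float(np.sign(diff.mean()) * np.inf), 0.0
    t, p = scipy.stats.ttest_rel(a, b)
    return float(t), float(p)


@dataclass
class TrendResult:
    """OLS fit of taxon ICC on log mean relative abundance."""

    slope: float
    intercept: float
    p_value: float
    n_taxa: int
    r_value: float = float("nan")


def abundance_icc_trend(taxa_iccs: Mapping[str, float],
                        taxa_abund: Mapping[str, float],
                        floor: float = 0.001,
                        floor_abund: Mapping[str, float] | None = None,
                        ) -> TrendResult:
    """Linear trend of reproducibility with taxon abundance.

    Regresses each taxon's ICC on the natural log of its mean relative
    abundance, restricted to taxa whose floor abundance (``floor_abund``,
    defaulting to ``taxa_abund`` itself) is at least ``floor`` (0.1% by
    default).  Returns the two-sided slope p-value.
    """
    if floor_abund is None:
        floor_abund = taxa_abund
    taxa = [t for t in taxa_iccs
            if t in taxa_abund and floor_abund.get(t, 0.0) >= floor]
    if len(taxa) < 3:
        raise ValueError(f"only {len(taxa)} taxa above the {floor:g} abundance "
                         "floor; need at least 3")
    x = np.log([taxa_abund[t] for t in taxa])
    y = np.array([taxa_iccs[t] for t in taxa], dtype=float)
    fit = scipy.stats.linregress(x, y)
    return TrendResult(slope=float(fit.slope), intercept=float(fit.intercept),
                       p_value=float(fit.pvalue), n_taxa=len(taxa),
                       r_value=float(fit.rvalue))
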