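"""Self-validation experiments: estimator recovery, test calibration,
and the study-level qualitative checks.

These routines re-derive the package's statistical guarantees by
simulation at the reference design (10 subjects × 3 replicates) and are
used both by the test suite and by the reproducibility script.  Each takes
an explicit seed and returns plain numbers.
"""

from __future__ import annotations

import numpy as np

from .alpha import alpha_with_rarefaction
from .icc import abundance_icc_trend, icc_oneway, temporal_icc
from .simulate import SyntheticParams, generate_gaussian_replicates, generate_study
from .tables import relative_abundance


def _subseed(seed: int, *key) -> int:
    """Collision-free 31-bit sub-seed for an experiment's s-th replicate."""
    state = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *key])
    return int(state.generate_state(1)[0] & 0x7FFFFFFF)


def icc_recovery_mean(sigma_b2: float, sigma_e2: float, n_sims: int = 500,
                      n_subjects: int = 10, k: int = 3, seed: int = 0) -> float:
    """Mean one-way ICC estimate over simulated Gaussian replicate studies.

    The true ICC is sigma_b2 / (sigma_b2 + sigma_e2); the ANOVA-moment
    estimator is nearly unbiased at this design, so the mean should sit
    within a few hundredths of the truth.
    """
    estimates = [
        icc_oneway(generate_gaussian_replicates(
            n_subjects, k, sigma_b2, sigma_e2,
            seed=_subseed(seed, 1, int(100 * sigma_b2), int(100 * sigma_e2), s)))
        .icc
        for s in range(n_sims)
    ]
    return float(np.mean(estimates))


def permutation_type_i_rate(n_sims: int = 200, n_perm: int = 199,
                            alpha: float = 0.05, n_subjects: int = 10,
                            k: int = 3, seed: int = 0) -> float:
    """Rejection rate of the ICC=0 permutation test when ICC is truly 0."""
    rejections = 0
    for s in range(n_sims):
        groups = generate_gaussian_replicates(
            n_subjects, k, 0.0, 1.0, seed=_subseed(seed, 2, s))
        res = icc_oneway(groups)
        if res.permutation_test(n_perm=n_perm,
                                seed=_subseed(seed, 3, s)) <= alpha:
            rejections += 1
    return rejections / n_sims


def _taxon_trend_slope(seed: int, rare_noise_scale: float = 1.0,
                       floor: float = 0.001) -> float:
    """Slope of per-taxon ICC vs log mean abundance, RNAlater at day 0."""
    study = generate_study(SyntheticParams(seed=seed,
                                           rare_noise_scale=rare_noise_scale))
    meta = study.metadata
    sids = meta.stratum(medium="rnalater", time_days=0)
    comp = relative_abundance(study.counts).data.loc[sids]
    median_ab = comp.median(axis=0)
    mean_ab = comp.mean(axis=0)
    subjects = meta.data.loc[sids, "subject_id"]
    iccs, means = {}, {}
    for otu in comp.columns:
        if median_ab[otu] < floor:
            continue
        grouped = [(g, list(v)) for g, v in comp[otu].groupby(subjects)]
        iccs[otu] = icc_oneway(grouped).icc_report
        means[otu] = float(mean_ab[otu])
    return abundance_icc_trend(iccs, means, floor=0.0).slope


def trend_positive_fraction(n_runs: int = 50, seed: int = 0,
                            rare_noise_scale: float = 1.0) -> float:
    """Fraction of simulated studies with a positive abundance-ICC slope.

    With replicate noise inflated for rare taxa, common taxa should be
    systematically more reproducible, so the slope should be positive in
    nearly every run.
    """
    hits = sum(_taxon_trend_slope(_subseed(seed, 4, r), rare_noise_scale) > 0
               for r in range(n_runs))
    return hits / n_runs


def _day7_richness_iccs(seed: int, depth: int = 5000, draws: int = 20):
    """Temporal (day 7 vs 0) richness ICC per RNAlater-based medium."""
    study = generate_study(SyntheticParams(seed=seed))
    meta = study.metadata
    media = ("rnalater", "rnalater_kan", "rnalater_cipro")
    keep = [s for s in meta.stratum(times=(0, 7))
            if meta.data.loc[s, "medium"] in media]
    sub = study.counts.subset(keep)
    res = alpha_with_rarefaction(sub, metrics=("observed_species",),
                                 depth=depth, draws=draws, seed=seed)
    vals = res.values["observed_species"]
    out = {}
    for medium in media:
        avgs = {}
        for t in (0, 7):
            sids = [s for s in keep
                    if meta.data.loc[s, "medium"] == medium
                    and meta.data.loc[s, "time_days"] == t]
            series = vals.loc[sids]
            avgs[t] = series.groupby(meta.data.loc[sids, "subject_id"]) \
                .mean().to_dict()
        out[medium] = temporal_icc(avgs[7], avgs[0]).icc
    return out


def drift_direction_fraction(n_runs: int = 50, seed: int = 0) -> float:
    """Fraction of runs where plain RNAlater keeps day-7 richness most stable.

    The generator's antibiotic media drift faster; a run counts as a hit
    when the day-7-vs-0 richness ICC under plain RNAlater exceeds both
    antibiotic media.
    """
    hits = 0
    for r in range(n_runs):
        iccs = _day7_richness_iccs(_subseed(seed, 5, r))
        if iccs["rnalater"] > iccs["rnalater_kan"] and \
                iccs["rnalater"] > iccs["rnalater_cipro"]:
            hits += 1
    return hits / n_runs
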