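"""Synthetic replicated-stool-study generator with known ground truth.

Emulates the reference design — 10 subjects, 30 aliquots each: 3 no-media
aliquots frozen immediately (day 0 only), and 3 replicates × {0, 3, 7} days
of room-temperature incubation for each of three RNAlater-based media
(plain, + kanamycin, + ciprofloxacin) — over a simulated OTU table whose
phylum composition targets typical stool (Firmicutes ~75%, Bacteroidetes
~15%, Actinobacteria ~2%, Proteobacteria ~0.6%, remainder "other").

Generative hierarchy (log-normal softmax multinomial):

1. a fixed power-law (Zipf, exponent 1.5) template of OTU log-abundances,
   partitioned by phylum so expected phylum totals match the targets;
2. per-subject baselines: template + N(0, sigma_b2) per OTU;
3. per-medium log fold-changes on whole phyla (e.g. Bacteroidetes
   depletion without preservation medium);
4. per-aliquot incubation drift N(0, drift_rate^2 * days) per OTU
   (Brownian in time, independent across aliquots);
5. per-aliquot replicate noise N(0, sigma_e2), optionally inflated for
   rare taxa;
6. softmax to a composition, then multinomial read sampling at a fixed
   depth.

Because sigma_b2 and sigma_e2 act on the log-abundance scale, the latent
(infinite-depth, Gaussian-trait) intraclass correlation is exactly
sigma_b2 / (sigma_b2 + sigma_e2), which makes parameter-recovery tests
interpretable.  All randomness is keyed by a single master seed with
per-sample substreams derived from (subject, medium, time, replicate), so
adding subjects does not reshuffle existing samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .tables import MEDIA, CountTable, SampleMetadata, TaxonomyMap
from .tree import PhyloTree

DEFAULT_PHYLUM_TARGETS: dict[str, float] = {
    "Firmicutes": 0.751,
    "Bacteroidetes": 0.146,
    "Actinobacteria": 0.021,
    "Proteobacteria": 0.006,
}

#: Log fold-changes applied per medium and phylum.  Without preservation
#: medium, Bacteroidetes drop sharply and Proteobacteria mildly; the
#: compensatory rise of the remaining phyla emerges from renormalization.
DEFAULT_MEDIUM_EFFECTS: dict[str, dict[str, float]] = {
    "none": {"Bacteroidetes": -1.6, "Proteobacteria": -0.6},
}

#: Per-day^(1/2) log-abundance drift s.d. during room-temperature
#: incubation; antibiotics destabilize rather than protect.
DEFAULT_DRIFT_RATES: dict[str, float] = {
    "none": 0.0,
    "rnalater": 0.10,
    "rnalater_kan": 0.25,
    "rnalater_cipro": 0.25,
}


@dataclass
class SyntheticParams:
    """Knobs of the synthetic study; defaults emulate the reference design."""

    n_subjects: int = 10
    n_otus: int = 200
    depth: int = 20_000
    sigma_b2: float = 1.0
    sigma_e2: float = 0.05
    medium_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_MEDIUM_EFFECTS.items()})
    drift_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DRIFT_RATES))
    phylum_targets: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHYLUM_TARGETS))
    rare_noise_scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_b2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be non-negative")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_otus < 4:
            raise ValueError("need at least 4 OTUs")
        if self.n_subjects < 1:
            raise ValueError("need at least 1 subject")
        total = sum(self.phylum_targets.values())
        if total > 1 + 1e-9:
            raise ValueError(f"phylum targets sum to {total} > 1")
        unknown = set(self.drift_rates) - set(MEDIA)
        if unknown:
            raise ValueError(f"drift rates for unknown media: {sorted(unknown)}")

    def _master(self) -> int:
        return int(self.seed) & 0x7FFFFFFF


@dataclass
class GroundTruth:
    """What the generator actually did — for parameter-recovery tests."""

    template_log_abundance: pd.Series          # per OTU, softmax-ready
    phylum_of: dict[str, str]
    subject_baselines: pd.DataFrame            # subjects × OTUs (log scale)
    true_gaussian_icc: float                   # sigma_b2 / (sigma_b2 + sigma_e2)
    medium_log_effects: pd.DataFrame           # media × OTUs
    noise_sd_multiplier: pd.Series             # per OTU
    params: SyntheticParams


class SyntheticStudy(NamedTuple):
    counts: CountTable
    metadata: SampleMetadata
    tree: PhyloTree
    taxonomy: TaxonomyMap
    truth: GroundTruth


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------

def generate_tree(n_otus: int, seed: int, names=None,
                  mean_branch_length: float = 0.1) -> PhyloTree:
    """Random rooted binary tree by successive random joins.

    Branch lengths are i.i.d. exponential with the given mean; a rooted
    binary tree over n leaves has 2n - 2 edges, so the expected total
    branch length is (2n - 2) * mean.
    """
    if n_otus < 2:
        raise ValueError("need at least 2 leaves")
    if names is None:
        names = [f"OTU_{i:04d}" for i in range(n_otus)]
    if len(names) != n_otus:
        raise ValueError("names length must equal n_otus")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 7])
    subtrees = list(names)
    while len(subtrees) > 1:
        i, j = rng.choice(len(subtrees), size=2, replace=False)
        i, j = sorted((int(i), int(j)))
        right = subtrees.pop(j)
        left = subtrees.pop(i)
        bl, br = rng.exponential(mean_branch_length, size=2)
        subtrees.append(f"({left}:{bl:.9g},{right}:{br:.9g})")
    return PhyloTree.from_newick(subtrees[0] + ";")


# ---------------------------------------------------------------------------
# template composition
# ---------------------------------------------------------------------------

def _allocate_otus(n_otus: int, targets: dict[str, float]) -> dict[str, int]:
    phyla = list(targets)
    other_share = max(0.0, 1.0 - sum(targets.values()))
    alloc = {p: max(2, int(round(n_otus * targets[p]))) for p in phyla}
    n_other = n_otus - sum(alloc.values())
    min_other = 2 if other_share > 0 else 0
    while n_other < min_other:
        # shave the largest allocation until "other" has room
        big = max(alloc, key=alloc.get)
        if alloc[big] <= 2:
            raise ValueError("n_otus too small for the phylum allocation")
        alloc[big] -= 1
        n_other += 1
    if min_other:
        alloc["other"] = n_other
    return alloc


def _template(n_otus: int, targets: dict[str, float],
              zipf_exponent: float = 1.5):
    """Power-law OTU weights, rescaled per phylum to hit the target shares."""
    alloc = _allocate_otus(n_otus, targets)
    shares = dict(targets)
    if "other" in alloc:
        shares["other"] = max(0.0, 1.0 - sum(targets.values()))
    otu_ids, weights, phylum_of = [], [], {}
    i = 0
    for phylum, n_p in alloc.items():
        ranks = np.arange(1, n_p + 1, dtype=float)
        w = ranks ** (-zipf_exponent)
        w = w / w.sum() * shares[phylum]
        for j in range(n_p):
            oid = f"OTU_{i:04d}"
            otu_ids.append(oid)
            weights.append(w[j])
            phylum_of[oid] = phylum
            i += 1
    weights = np.asarray(weights)
    weights = weights / weights.sum()
    return otu_ids, weights, phylum_of


# ---------------------------------------------------------------------------
# study generation
# ---------------------------------------------------------------------------

def design_cells(n_subjects: int):
    """The reference design: (subject index, medium, time, replicate)."""
    for s in range(n_subjects):
        for rep in (1, 2, 3):
            yield s, "none", 0, rep
        for medium in ("rnalater", "rnalater_kan", "rnalater_cipro"):
            for days in (0, 3, 7):
                for rep in (1, 2, 3):
                    yield s, medium, days, rep


def generate_study(params: SyntheticParams | None = None, **kwargs) -> SyntheticStudy:
    """Generate a full synthetic study (counts, metadata, tree, taxonomy, truth)."""
    if params is None:
        params = SyntheticParams(**kwargs)
    elif kwargs:
        raise TypeError("pass either params or keyword overrides, not both")
    master = params._master()

    otu_ids, template_p, phylum_of = _template(params.n_otus, params.phylum_targets)
    log_template = np.log(template_p)
    tree = generate_tree(params.n_otus, seed=master, names=otu_ids)

    # per-OTU replicate-noise multiplier: taxa below 1% get one extra unit
    # of s.d. per decade of rarity when rare_noise_scale > 0
    decades_below = np.maximum(0.0, np.log10(0.01 / template_p))
    noise_mult = 1.0 + params.rare_noise_scale * decades_below

    media_order = [m for m in MEDIA]
    effect_rows = {}
    for medium in media_order:
        eff = np.zeros(params.n_otus)
        for phylum, lfc in params.medium_effects.get(medium, {}).items():
            mask = np.array([phylum_of[o] == phylum for o in otu_ids])
            eff[mask] = lfc
        effect_rows[medium] = eff

    sd_b = float(np.sqrt(params.sigma_b2))
    sd_e = float(np.sqrt(params.sigma_e2))
    baselines = np.empty((params.n_subjects, params.n_otus))
    for s in range(params.n_subjects):
        rng = np.random.default_rng([master, 101, s])
        baselines[s] = log_template + rng.normal(0.0, sd_b, params.n_otus)

    med_index = {m: i for i, m in enumerate(media_order)}
    sample_ids, meta_rows, count_rows = [], [], []
    for s, medium, days, rep in design_cells(params.n_subjects):
        subj = f"subj{s + 1:02d}"
        sid = f"{subj}.{medium}.t{days}.r{rep}"
        rng = np.random.default_rng([master, 202, s, med_index[medium], days, rep])
        eta = baselines[s] + effect_rows[medium]
        rate = params.drift_rates.get(medium, 0.0)
        if days > 0 and rate > 0:
            eta = eta + rng.normal(0.0, rate * np.sqrt(days), params.n_otus)
        elif days > 0:
            rng.normal(0.0, 1.0, params.n_otus)  # keep stream alignment
        if sd_e > 0:
            eta = eta + rng.normal(0.0, sd_e, params.n_otus) * noise_mult
        p = np.exp(eta - eta.max())
        p /= p.sum()
        count_rows.append(rng.multinomial(params.depth, p))
        sample_ids.append(sid)
        meta_rows.append((subj, medium, days, rep))

    counts = CountTable(pd.DataFrame(
        np.asarray(count_rows, dtype=np.int64), index=sample_ids, columns=otu_ids))
    counts.data.index.name = "sample_id"
    meta = SampleMetadata(pd.DataFrame(
        meta_rows, index=pd.Index(sample_ids, name="sample_id"),
        columns=["subject_id", "medium", "time_days", "replicate"]))
    taxonomy = TaxonomyMap(dict(phylum_of))
    sigma_tot = params.sigma_b2 + params.sigma_e2
    truth = GroundTruth(
        template_log_abundance=pd.Series(log_template, index=otu_ids),
        phylum_of=dict(phylum_of),
        subject_baselines=pd.DataFrame(
            baselines, index=[f"subj{s + 1:02d}" for s in range(params.n_subjects)],
            columns=otu_ids),
        true_gaussian_icc=params.sigma_b2 / sigma_tot if sigma_tot > 0 else float("nan"),
        medium_log_effects=pd.DataFrame(effect_rows, index=otu_ids).T,
        noise_sd_multiplier=pd.Series(noise_mult, index=otu_ids),
        params=params,
    )
    return SyntheticStudy(counts, meta, tree, taxonomy, truth)


def generate_gaussian_replicates(n_subjects: int, k: int, sigma_b2: float,
                                 sigma_e2: float, seed: int):
    """Direct simulation of the one-way random-effects model.

    value_ij = b_i + e_ij with b_i ~ N(0, sigma_b2), e_ij ~ N(0, sigma_e2);
    the true ICC is sigma_b2 / (sigma_b2 + sigma_e2).  Returns grouped
    values suitable for :func:`replistool.icc.icc_oneway`.
    """
    if n_subjects < 2 or k < 2:
        raise ValueError("need n_subjects >= 2 and k >= 2")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    effects = rng.normal(0.0, np.sqrt(sigma_b2), n_subjects)
    out = []
    for i in range(n_subjects):
        noise = rng.normal(0.0, np.sqrt(sigma_e2), k)
        out.append((f"S{i + 1}", list(effects[i] + noise)))
    return out
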