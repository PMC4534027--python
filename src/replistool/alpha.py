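"""Alpha diversity under repeated rarefaction.

Four within-sample diversity metrics are supported — observed species
(richness), bias-corrected Chao1, the Shannon index (natural log), and
Faith's phylogenetic diversity (PD whole tree) — each averaged over repeated
random subsamples ("rarefactions") of a fixed read depth drawn without
replacement, which removes sequencing-depth bias between samples.  The
default scheme is 20 draws of 5000 reads per sample.  Samples whose total
read count falls below the rarefaction depth are excluded (never silently
subsampled at a smaller depth).

Rarefaction draws follow the multivariate hypergeometric law (sampling reads
without replacement), with one RNG substream per (sample, draw) so a
sample's values do not depend on table ordering.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import CountTable
from .tree import PhyloTree

logger = logging.getLogger(__name__)

METRICS = ("observed_species", "chao1", "shannon", "pd")

DEFAULT_DEPTH = 5000
DEFAULT_DRAWS = 20


def rarefy(counts, depth: int, seed) -> np.ndarray:
    """Subsample a count vector to ``depth`` reads without replacement.

    The result follows the multivariate hypergeometric distribution; each
    entry is bounded by the original entry and the result sums exactly to
    ``depth``.  Raises ``ValueError`` when the sample has fewer than
    ``depth`` reads (callers mark such samples excluded).
    """
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if total < depth:
        raise ValueError(f"sample has {total} reads, below rarefaction depth {depth}")
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth)


def observed_species(counts) -> int:
    """Number of OTUs with at least one read."""
    return int(np.count_nonzero(np.asarray(counts)))


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S + F1(F1-1) / (2(F2+1)).

    F1 and F2 are the numbers of singleton and doubleton OTUs.  With no
    singletons the estimate equals the observed richness.
    """
    counts = np.asarray(counts)
    s_obs = np.count_nonzero(counts)
    f1 = int(np.count_nonzero(counts == 1))
    f2 = int(np.count_nonzero(counts == 2))
    return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def shannon(counts) -> float:
    """Shannon index H = -sum(p_i ln p_i) over OTUs with positive counts."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero sample")
    p = counts[counts > 0] / total
    return float(-np.sum(p * np.log(p)))


def faith_pd(presence, tree: PhyloTree, include_root: bool = True) -> float:
    """Faith's phylogenetic diversity of a set of present OTUs.

    Sum of branch lengths of the minimal subtree connecting the present
    leaves; with ``include_root=True`` (default) the subtree is anchored at
    the root, so a single leaf scores its full root-path length.
    """
    present = set(presence)
    if not present:
        return 0.0
    missing = present - set(tree.leaf_names)
    if missing:
        raise KeyError(f"OTUs absent from tree: {sorted(missing)}")
    leaf_order = tree.leaf_names
    lengths, incidence = tree.branch_arrays(leaf_order)
    mask = np.array([name in present for name in leaf_order])
    n_below = incidence @ mask.astype(np.int64)
    if include_root:
        used = n_below > 0
    else:
        # only edges inside the spanning subtree of the present leaves
        used = (n_below > 0) & (n_below < mask.sum())
    return float(lengths[used].sum())


_METRIC_FUNCS = {
    "observed_species": lambda v, _tree: float(observed_species(v)),
    "chao1": lambda v, _tree: chao1(v),
    "shannon": lambda v, _tree: shannon(v),
}


@dataclass
class AlphaResult:
    """Per-sample rarefied alpha diversity.

    ``values`` holds the mean over rarefaction draws (NaN for excluded
    samples); ``excluded`` flags samples under the rarefaction depth.
    """

    values: pd.DataFrame      # samples × metrics
    excluded: pd.Series       # bool per sample
    depth: int
    draws: int


def _sample_stream(seed, sample_id: str, draw: int):
    # keyed by sample *id*, not position, so results survive row reordering
    return [int(seed) & 0x7FFFFFFF, zlib.crc32(sample_id.encode()), draw]


def alpha_with_rarefaction(
    table: CountTable,
    metrics=METRICS,
    depth: int = DEFAULT_DEPTH,
    draws: int = DEFAULT_DRAWS,
    seed: int = 0,
    tree: PhyloTree | None = None,
    include_root: bool = True,
) -> AlphaResult:
    """Rarefied alpha diversity: each metric averaged over ``draws`` draws.

    ``tree`` is required when ``'pd'`` is among the metrics; it is pruned to
    the table's OTU set before traversal.
    """
    if isinstance(metrics, str):
        metrics = (metrics,)
    unknown = set(metrics) - set(METRICS)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}; choose from {METRICS}")

    want_pd = "pd" in metrics
    lengths = incidence = None
    if want_pd:
        if tree is None:
            raise ValueError("metric 'pd' requires a phylogenetic tree")
        tree = tree.prune_to(table.otu_ids) if set(tree.leaf_names) != set(table.otu_ids) else tree
        lengths, incidence = tree.branch_arrays(table.otu_ids)

    counts = table.counts
    totals = counts.sum(axis=1)
    excluded = pd.Series(totals < depth, index=table.data.index, name="excluded")
    n_exc = int(excluded.sum())
    if n_exc:
        logger.warning(
            "%d sample(s) below rarefaction depth %d excluded: %s",
            n_exc, depth, list(excluded.index[excluded]),
        )

    out = np.full((len(table.sample_ids), len(metrics)), np.nan)
    for i, sid in enumerate(table.sample_ids):
        if excluded.iloc[i]:
            continue
        acc = np.zeros(len(metrics))
        for d in range(draws):
            sub = rarefy(counts[i], depth, _sample_stream(seed, sid, d))
            for m, metric in enumerate(metrics):
                if metric == "pd":
                    n_below = incidence @ (sub > 0).astype(np.int64)
                    acc[m] += float(lengths[n_below > 0].sum()) if include_root \
                        else float(lengths[(n_below > 0) & (n_below < (sub > 0).sum())].sum())
                else:
                    acc[m] += _METRIC_FUNCS[metric](sub, None)
        out[i] = acc / draws

    values = pd.DataFrame(out, index=table.data.index, columns=list(metrics))
    return AlphaResult(values=values, excluded=excluded, depth=depth, draws=draws)
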