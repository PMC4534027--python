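"""Beta diversity: UniFrac distances, principal coordinates, distance R².

UniFrac measures the phylogenetic dissimilarity of two communities as the
fraction (unweighted) or abundance-weighted sum (weighted) of branch length
unique to one community.  The weighted form here is the *raw* one,
``sum_e b_e |P_A(e) - P_B(e)|`` where ``P_X(e)`` is the fraction of
community X's abundance descending through edge e; an optional
normalization divides by the maximum attainable value.

Distance matrices are embedded with classical PCoA (Gower double-centering
followed by eigendecomposition); the distance-based coefficient of
determination R² decomposes total squared pairwise distance into between-
and within-group parts (the one-factor PERMANOVA decomposition).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from skbio.stats.distance import DistanceMatrix

from .alpha import rarefy
from .tables import CountTable
from .tree import PhyloTree

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# per-edge machinery
# ---------------------------------------------------------------------------

def _edge_arrays(tree: PhyloTree, otu_ids):
    otu_ids = list(otu_ids)
    if set(tree.leaf_names) != set(otu_ids):
        tree = tree.prune_to(otu_ids)
    return tree.branch_arrays(otu_ids)


def _as_vector(abund, otu_ids) -> np.ndarray:
    if isinstance(abund, dict):
        extra = set(abund) - set(otu_ids)
        if extra:
            raise KeyError(f"abundance on leaves absent from tree: {sorted(extra)}")
        return np.array([float(abund.get(o, 0.0)) for o in otu_ids])
    vec = np.asarray(abund, dtype=float)
    if vec.shape != (len(otu_ids),):
        raise ValueError("abundance vector length must match the tree's leaf count")
    return vec


def unweighted_unifrac(presence_a, presence_b, tree: PhyloTree) -> float:
    """Unweighted UniFrac distance between two presence sets.

    Unique branch length (leading to exactly one community) divided by
    total branch length leading to either community.
    """
    set_a, set_b = set(presence_a), set(presence_b)
    if not set_a and not set_b:
        raise ValueError("both communities are empty")
    leaves = set(tree.leaf_names)
    missing = (set_a | set_b) - leaves
    if missing:
        raise KeyError(f"OTUs absent from tree: {sorted(missing)}")
    lengths, incidence = _edge_arrays(tree, tree.leaf_names)
    names = tree.leaf_names
    in_a = np.array([n in set_a for n in names])
    in_b = np.array([n in set_b for n in names])
    to_a = incidence @ in_a > 0
    to_b = incidence @ in_b > 0
    union = float(lengths[to_a | to_b].sum())
    if union == 0:
        return 0.0
    unique = float(lengths[to_a ^ to_b].sum())
    return unique / union


def weighted_unifrac(abund_a, abund_b, tree: PhyloTree,
                     normalized: bool = False) -> float:
    """Raw weighted UniFrac distance between two composition vectors.

    Each vector must sum to 1 over the tree's leaves (dict or array aligned
    to ``tree.leaf_names``).  With ``normalized=True`` the raw distance is
    divided by its maximum attainable value, ``sum_e b_e (P_A(e)+P_B(e))``.
    """
    names = tree.leaf_names
    va = _as_vector(abund_a, names)
    vb = _as_vector(abund_b, names)
    for label, v in (("a", va), ("b", vb)):
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"composition {label} sums to {v.sum()}, expected 1")
    lengths, incidence = _edge_arrays(tree, names)
    pa = incidence @ va
    pb = incidence @ vb
    raw = float(np.sum(lengths * np.abs(pa - pb)))
    if not normalized:
        return raw
    denom = float(np.sum(lengths * (pa + pb)))
    return raw / denom if denom > 0 else 0.0


def unifrac_matrix(
    table: CountTable,
    tree: PhyloTree,
    kind: str = "weighted",
    depth: int | None = 5000,
    seed: int = 0,
    normalized: bool = False,
) -> DistanceMatrix:
    """All-pairs UniFrac distances after a single rarefaction per sample.

    Samples are subsampled once to ``depth`` reads (``depth=None`` computes
    on the full counts); unweighted UniFrac uses post-rarefaction presence,
    weighted uses post-rarefaction composition.  Samples under ``depth`` are
    dropped with a warning.
    """
    if kind not in ("weighted", "unweighted"):
        raise ValueError("kind must be 'weighted' or 'unweighted'")
    counts = table.counts
    sample_ids = table.sample_ids
    keep = np.ones(len(sample_ids), dtype=bool)
    if depth is not None:
        totals = counts.sum(axis=1)
        keep = totals >= depth
        if not keep.all():
            dropped = [s for s, k in zip(sample_ids, keep) if not k]
            logger.warning("%d sample(s) under depth %d dropped from UniFrac: %s",
                           len(dropped), depth, dropped)
        rows = []
        for i in np.flatnonzero(keep):
            sub_seed = [int(seed) & 0x7FFFFFFF,
                        zlib.crc32(b"beta:" + sample_ids[i].encode())]
            rows.append(rarefy(counts[i], depth, sub_seed))
        counts = np.asarray(rows)
        sample_ids = [s for s, k in zip(sample_ids, keep) if k]

    if set(tree.leaf_names) != set(table.otu_ids):
        tree = tree.prune_to(table.otu_ids)
    lengths, incidence = tree.branch_arrays(table.otu_ids)
    inc = incidence.astype(float)

    if kind == "unweighted":
        through = (counts > 0).astype(float) @ inc.T > 0      # samples × edges
        weighted_presence = through * lengths                  # b_e on used edges
        shared = weighted_presence @ through.T
        totals = weighted_presence.sum(axis=1)
        union = totals[:, None] + totals[None, :] - shared
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(union > 0, (union - shared) / union, 0.0)
    else:
        comp = counts / counts.sum(axis=1, keepdims=True)
        flow = comp @ inc.T                                    # samples × edges
        scaled = flow * lengths
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(scaled, metric="cityblock"))
        if normalized:
            denom = scaled.sum(axis=1)
            pair = denom[:, None] + denom[None, :]
            with np.errstate(invalid="ignore", divide="ignore"):
                d = np.where(pair > 0, d / pair, 0.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(d, ids=sample_ids)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class PCoAResult:
    """Principal-coordinate embedding of a distance matrix.

    ``coordinates`` holds one column per retained axis (positive
    eigenvalues only); ``proportion_explained`` is relative to the sum of
    positive eigenvalues.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    @property
    def sample_ids(self) -> list[str]:
        return list(self.coordinates.index)


def pcoa(dm: DistanceMatrix, n_axes: int = 3) -> PCoAResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Gower-centers the squared distances, eigendecomposes, and returns the
    ``n_axes`` leading positive axes scaled by sqrt(eigenvalue).  Negative
    eigenvalues (non-Euclidean input) are dropped, not corrected, and noted
    in the log.  Axis signs follow a fixed convention — the sample with the
    largest absolute coordinate on each axis is made positive — so repeated
    runs produce identical output.
    """
    d = dm.data
    n = d.shape[0]
    d2 = d ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centering @ d2 @ centering
    eigvals, eigvecs = scipy.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = max(1e-10, 1e-10 * abs(eigvals).max()) if n else 0.0
    positive = eigvals > tol
    n_pos = int(positive.sum())
    n_neg = int((eigvals < -tol).sum())
    if n_neg:
        logger.info("PCoA: %d negative eigenvalue(s) dropped (non-Euclidean input)",
                    n_neg)
    if n_axes > n_pos:
        logger.warning("PCoA: requested %d axes but only %d positive eigenvalues",
                       n_axes, n_pos)
    k = min(n_axes, n_pos)
    lam = eigvals[:k]
    coords = eigvecs[:, :k] * np.sqrt(lam)
    for j in range(k):
        idx = np.argmax(np.abs(coords[:, j]))
        if coords[idx, j] < 0:
            coords[:, j] = -coords[:, j]
    pos_sum = eigvals[positive].sum()
    prop = lam / pos_sum if pos_sum > 0 else np.zeros(k)
    cols = [f"PCoA{j + 1}" for j in range(k)]
    frame = pd.DataFrame(coords, index=list(dm.ids), columns=cols)
    return PCoAResult(coordinates=frame, eigenvalues=lam,
                      proportion_explained=prop)


def pcoa_full_embedding(dm: DistanceMatrix) -> PCoAResult:
    """PCoA retaining every positive axis (for embedding diagnostics)."""
    return pcoa(dm, n_axes=dm.shape[0])


# ---------------------------------------------------------------------------
# distance-based R²
# ---------------------------------------------------------------------------

@dataclass
class R2Result:
    """One-factor decomposition of total squared pairwise distance."""

    r2: float
    ss_total: float
    ss_within: float
    ss_between: float
    grouping_name: str
    n_groups: int


def variance_explained_r2(dm: DistanceMatrix, grouping,
                          grouping_name: str = "group") -> R2Result:
    """Fraction of squared pairwise distance explained by a grouping.

    ``ss_total = (1/N) sum_{i<j} d_ij²``;
    ``ss_within = sum_g (1/n_g) sum_{i<j in g} d_ij²``;
    ``r2 = 1 - ss_within / ss_total``.  Singleton groups contribute zero
    within-group sum of squares.
    """
    ids = list(dm.ids)
    if callable(grouping):
        labels = [grouping(s) for s in ids]
    else:
        labels = [grouping[s] for s in ids]
    if any(lbl is None for lbl in labels):
        raise ValueError("every sample must be labelled")
    groups = sorted(set(labels), key=str)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for a distance R²")
    d2 = dm.data ** 2
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    ss_total = float(d2[iu].sum()) / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(np.array([lbl == g for lbl in labels]))
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        su = np.triu_indices(len(idx), k=1)
        ss_within += float(sub[su].sum()) / len(idx)
    ss_between = ss_total - ss_within
    r2 = 1.0 - ss_within / ss_total if ss_total > 0 else 1.0
    return R2Result(r2=r2, ss_total=ss_total, ss_within=ss_within,
                    ss_between=ss_between, grouping_name=grouping_name,
                    n_groups=len(groups))
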