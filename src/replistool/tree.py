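"""Rooted phylogenetic trees over OTU leaves.

``PhyloTree`` is a validated wrapper around a scikit-bio ``TreeNode`` that
exposes the flat per-branch arrays the diversity code consumes: one edge per
non-root node, its branch length, and the boolean incidence of each leaf
below it.  Missing branch lengths default to 0; the (implicit) root edge has
length 0.  An unrooted-style trifurcation at the root is accepted as-is and
treated as the root; no re-rooting is attempted.
"""

from __future__ import annotations

import io

import numpy as np
from skbio import TreeNode


class NewickParseError(ValueError):
    """Raised for malformed Newick input or invalid tree structure."""


class PhyloTree:
    """Rooted tree with non-negative branch lengths and unique leaf labels."""

    def __init__(self, root: TreeNode):
        self._root = root
        names = [tip.name for tip in root.tips()]
        if root.is_tip():
            names = [root.name]
        if any(n is None for n in names):
            raise NewickParseError("every leaf must be labelled")
        if len(set(names)) != len(names):
            dups = sorted({n for n in names if names.count(n) > 1})
            raise NewickParseError(f"duplicate leaf labels: {dups}")
        for node in root.traverse(include_self=True):
            if node.length is None:
                node.length = 0.0
            if node.length < 0:
                raise NewickParseError(
                    f"negative branch length {node.length} at node {node.name!r}"
                )
        self._leaf_names = names

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            # convert_underscores=False: leaf labels are exact OTU ids
            root = TreeNode.read(io.StringIO(text), format="newick",
                                 convert_underscores=False)
        except Exception as exc:  # skbio raises NewickFormatError subclasses
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        return cls(root)

    @classmethod
    def read(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    # -- serialization ------------------------------------------------------

    def to_newick(self) -> str:
        buf = io.StringIO()
        self._root.write(buf, format="newick")
        return buf.getvalue().strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -- basic queries ------------------------------------------------------

    @property
    def leaf_names(self) -> list[str]:
        return list(self._leaf_names)

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_names)

    @property
    def n_edges(self) -> int:
        return sum(1 for n in self._root.traverse(include_self=False))

    def total_branch_length(self) -> float:
        return float(sum(n.length for n in self._root.traverse(include_self=False)))

    # -- manipulation -------------------------------------------------------

    def prune_to(self, leaf_subset) -> "PhyloTree":
        """Restrict the tree to ``leaf_subset``, merging degree-one paths.

        Branch lengths along collapsed paths are summed, so path lengths
        between retained leaves (and to the root) are preserved.
        """
        keep = set(leaf_subset)
        missing = keep - set(self._leaf_names)
        if missing:
            raise KeyError(f"leaves not in tree: {sorted(missing)}")
        if len(keep) < 2:
            raise ValueError("prune_to requires at least 2 leaves")
        sheared = self._root.shear(keep)
        return PhyloTree(sheared)

    # -- flat edge arrays ---------------------------------------------------

    def branch_arrays(self, leaf_order) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(lengths, incidence)`` for all non-root edges.

        ``lengths`` has shape (E,); ``incidence`` is boolean with shape
        (E, L) where entry (e, j) is True when leaf ``leaf_order[j]``
        descends through edge e.  ``leaf_order`` must be a permutation of a
        subset of the leaf labels covering all leaves (use :meth:`prune_to`
        first if the table's OTU set is smaller than the tree's).
        """
        leaf_order = list(leaf_order)
        if set(leaf_order) != set(self._leaf_names):
            raise ValueError(
                "leaf_order must cover exactly the tree's leaves; "
                "prune the tree to the OTU set first"
            )
        index = {name: j for j, name in enumerate(leaf_order)}
        n_leaf = len(leaf_order)
        lengths: list[float] = []
        rows: list[np.ndarray] = []
        below: dict[int, np.ndarray] = {}
        for node in self._root.postorder(include_self=True):
            if node.is_tip():
                mask = np.zeros(n_leaf, dtype=bool)
                mask[index[node.name]] = True
            else:
                mask = np.zeros(n_leaf, dtype=bool)
                for child in node.children:
                    mask |= below[id(child)]
            below[id(node)] = mask
            if node is not self._root:
                lengths.append(float(node.length))
                rows.append(mask)
        return np.asarray(lengths), np.asarray(rows)
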