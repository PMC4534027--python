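"""UniFrac distances, PCoA embedding, and distance-based R²."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from oracles import (r2_oracle, random_nested_tree, to_newick,
                     unweighted_unifrac_oracle, weighted_unifrac_oracle)
from replistool import (CountTable, PhyloTree, pcoa, unifrac_matrix,
                        unweighted_unifrac, variance_explained_r2,
                        weighted_unifrac)


def _random_presence(rng, names):
    mask = rng.random(len(names)) < 0.5
    if not mask.any():
        mask[rng.integers(len(names))] = True
    return {n for n, m in zip(names, mask) if m}


def _random_composition(rng, names):
    w = rng.dirichlet(np.ones(len(names)))
    # zero out some leaves to exercise sparsity
    drop = rng.random(len(names)) < 0.3
    if drop.all():
        drop[0] = False
    w[drop] = 0
    w /= w.sum()
    return dict(zip(names, w))


class TestUnweightedUniFrac:
    def test_identical_communities_give_zero(self, three_leaf_tree):
        assert unweighted_unifrac({"A", "B"}, {"A", "B"},
                                  three_leaf_tree) == 0.0

    def test_disjoint_clades_give_one(self, four_leaf_tree):
        assert unweighted_unifrac({"A", "B"}, {"C", "D"},
                                  four_leaf_tree) == pytest.approx(1.0)

    def test_both_empty_raise(self, three_leaf_tree):
        with pytest.raises(ValueError):
            unweighted_unifrac(set(), set(), three_leaf_tree)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            nested = random_nested_tree(rng, int(rng.integers(3, 17)))
            tree = PhyloTree.from_newick(to_newick(nested))
            a = _random_presence(rng, tree.leaf_names)
            b = _random_presence(rng, tree.leaf_names)
            got = unweighted_unifrac(a, b, tree)
            want = unweighted_unifrac_oracle(a, b, nested)
            assert got == pytest.approx(want, abs=1e-12)
            assert 0.0 <= got <= 1.0
            assert unweighted_unifrac(b, a, tree) == pytest.approx(got)


class TestWeightedUniFrac:
    def test_identical_compositions_give_zero(self, four_leaf_tree):
        comp = {"A": 0.5, "B": 0.25, "C": 0.25}
        assert weighted_unifrac(comp, dict(comp),
                                four_leaf_tree) == pytest.approx(0.0)

    def test_two_leaf_hand_computation(self):
        tree = PhyloTree.from_newick("(A:1,B:1);")
        assert weighted_unifrac({"A": 1.0}, {"B": 1.0},
                                tree) == pytest.approx(2.0)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            nested = random_nested_tree(rng, int(rng.integers(3, 17)))
            tree = PhyloTree.from_newick(to_newick(nested))
            a = _random_composition(rng, tree.leaf_names)
            b = _random_composition(rng, tree.leaf_names)
            got = weighted_unifrac(a, b, tree)
            want = weighted_unifrac_oracle(a, b, nested)
            assert got == pytest.approx(want, abs=1e-12)
            assert weighted_unifrac(b, a, tree) == pytest.approx(got)

    def test_invariant_to_branch_subdivision(self):
        whole = PhyloTree.from_newick("((A:1,B:1):2,C:2);")
        # split the internal branch of length 2 into 1 + 1
        split = PhyloTree.from_newick("(((A:1,B:1):1):1,C:2);")
        a = {"A": 0.6, "C": 0.4}
        b = {"B": 0.9, "C": 0.1}
        assert weighted_unifrac(a, b, whole) == pytest.approx(
            weighted_unifrac(a, b, split), abs=1e-12)

    def test_abundance_off_tree_raises(self, three_leaf_tree):
        with pytest.raises(KeyError):
            weighted_unifrac({"X": 1.0}, {"A": 1.0}, three_leaf_tree)

    def test_unnormalized_composition_rejected(self, three_leaf_tree):
        with pytest.raises(ValueError, match="sums to"):
            weighted_unifrac({"A": 0.4}, {"B": 1.0}, three_leaf_tree)


class TestUniFracMatrix:
    def _study(self, rng, n_samples=6, n_otus=10, total=200):
        counts = rng.multinomial(total, rng.dirichlet(np.ones(n_otus)),
                                 size=n_samples)
        names = [f"OTU_{j:04d}" for j in range(n_otus)]
        table = CountTable(pd.DataFrame(
            counts, index=[f"s{i}" for i in range(n_samples)], columns=names))
        from replistool import generate_tree
        return table, generate_tree(n_otus, seed=11, names=names)

    @pytest.mark.parametrize("kind", ["weighted", "unweighted"])
    def test_symmetric_zero_diagonal_deterministic(self, kind, rng):
        table, tree = self._study(rng)
        dm1 = unifrac_matrix(table, tree, kind=kind, depth=100, seed=4)
        dm2 = unifrac_matrix(table, tree, kind=kind, depth=100, seed=4)
        np.testing.assert_array_equal(dm1.data, dm2.data)
        assert np.allclose(dm1.data, dm1.data.T)
        assert np.all(np.diag(dm1.data) == 0)
        assert dm1.data.min() >= 0

    def test_duplicate_rows_distance_zero_without_rarefaction(self, rng):
        table, tree = self._study(rng, n_samples=2)
        dup = CountTable(pd.DataFrame(
            np.vstack([table.counts[0], table.counts[0]]),
            index=["a", "b"], columns=table.otu_ids))
        for kind in ("weighted", "unweighted"):
            dm = unifrac_matrix(dup, tree, kind=kind, depth=None, seed=0)
            assert dm["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_pairwise_functions_without_rarefaction(self, rng):
        table, tree = self._study(rng, n_samples=4)
        dm_w = unifrac_matrix(table, tree, kind="weighted", depth=None, seed=0)
        dm_u = unifrac_matrix(table, tree, kind="unweighted", depth=None,
                              seed=0)
        comp = table.counts / table.counts.sum(axis=1, keepdims=True)
        for i in range(4):
            for j in range(i + 1, 4):
                a = dict(zip(table.otu_ids, comp[i]))
                b = dict(zip(table.otu_ids, comp[j]))
                assert dm_w[i, j] == pytest.approx(
                    weighted_unifrac(a, b, tree), abs=1e-12)
                pa = {o for o, c in zip(table.otu_ids, table.counts[i]) if c}
                pb = {o for o, c in zip(table.otu_ids, table.counts[j]) if c}
                assert dm_u[i, j] == pytest.approx(
                    unweighted_unifrac(pa, pb, tree), abs=1e-12)

    def test_agrees_with_skbio_reference(self, rng):
        """Cross-check the full-count matrices against scikit-bio's UniFrac."""
        skbio_div = pytest.importorskip("skbio.diversity")
        table, tree = self._study(rng, n_samples=5, n_otus=8)
        import io
        from skbio import TreeNode
        sk_tree = TreeNode.read(io.StringIO(tree.to_newick()),
                                convert_underscores=False)
        ref_u = skbio_div.beta_diversity(
            "unweighted_unifrac", table.counts, ids=table.sample_ids,
            taxa=table.otu_ids, tree=sk_tree)
        got_u = unifrac_matrix(table, tree, kind="unweighted", depth=None,
                               seed=0)
        np.testing.assert_allclose(got_u.data, ref_u.data, atol=1e-10)
        ref_w = skbio_div.beta_diversity(
            "weighted_unifrac", table.counts, ids=table.sample_ids,
            taxa=table.otu_ids, tree=sk_tree)
        got_w = unifrac_matrix(table, tree, kind="weighted", depth=None,
                               seed=0)
        np.testing.assert_allclose(got_w.data, ref_w.data, atol=1e-10)


class TestPCoA:
    def test_collinear_points_explain_all_on_axis_one(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        dm = DistanceMatrix(squareform(pdist(pts)), ids=["a", "b", "c"])
        res = pcoa(dm, n_axes=3)
        assert res.proportion_explained[0] == pytest.approx(1.0, abs=1e-9)
        assert res.coordinates.shape[1] == 1  # only one positive axis

    def test_planar_points_reconstructed(self, rng):
        pts = rng.normal(size=(5, 2))
        dm = DistanceMatrix(squareform(pdist(pts)),
                            ids=[f"s{i}" for i in range(5)])
        res = pcoa(dm, n_axes=5)
        coords = res.coordinates.to_numpy()
        rebuilt = squareform(pdist(coords))
        np.testing.assert_allclose(rebuilt, dm.data, atol=1e-9)

    def test_identical_points_give_zero_coordinates(self):
        dm = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        res = pcoa(dm, n_axes=3)
        assert res.coordinates.shape[1] == 0

    def test_sign_convention_is_deterministic(self, rng):
        pts = rng.normal(size=(6, 3))
        dm = DistanceMatrix(squareform(pdist(pts)),
                            ids=[f"s{i}" for i in range(6)])
        res = pcoa(dm, n_axes=3)
        for col in res.coordinates.columns:
            axis = res.coordinates[col].to_numpy()
            assert axis[np.argmax(np.abs(axis))] > 0


class TestVarianceExplainedR2:
    def test_identical_points_within_groups_give_one(self):
        pts = np.array([[0, 0], [0, 0], [5, 5], [5, 5]], dtype=float)
        dm = DistanceMatrix(squareform(pdist(pts)), ids=list("abcd"))
        res = variance_explained_r2(dm, {"a": "g1", "b": "g1",
                                         "c": "g2", "d": "g2"})
        assert res.r2 == pytest.approx(1.0)

    def test_crosswise_toy_configuration(self):
        # square of side 1: grouping along diagonals mixes near and far pairs
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        dm = DistanceMatrix(squareform(pdist(pts)), ids=list("abcd"))
        labels = {"a": "x", "c": "x", "b": "y", "d": "y"}
        res = variance_explained_r2(dm, labels)
        sst, ssw, r2 = r2_oracle(dm.data, [labels[i] for i in dm.ids])
        assert res.ss_total == pytest.approx(sst, abs=1e-12)
        assert res.ss_within == pytest.approx(ssw, abs=1e-12)
        assert res.r2 == pytest.approx(r2, abs=1e-12)

    def test_random_configurations_match_oracle(self, rng):
        for _ in range(10):
            n = 12
            pts = rng.normal(size=(n, 3))
            dm = DistanceMatrix(squareform(pdist(pts)),
                                ids=[f"s{i}" for i in range(n)])
            labels = {f"s{i}": f"g{rng.integers(3)}" for i in range(n)}
            if len(set(labels.values())) < 2:
                continue
            res = variance_explained_r2(dm, labels)
            sst, ssw, r2 = r2_oracle(dm.data, [labels[i] for i in dm.ids])
            assert res.ss_between + res.ss_within == pytest.approx(
                res.ss_total, abs=1e-9)
            assert res.r2 == pytest.approx(r2, abs=1e-12)
            assert 0.0 <= res.r2 <= 1.0 + 1e-12

    def test_single_group_raises(self):
        dm = DistanceMatrix(np.zeros((3, 3)), ids=list("abc"))
        with pytest.raises(ValueError, match="2 groups"):
            variance_explained_r2(dm, {"a": "g", "b": "g", "c": "g"})
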