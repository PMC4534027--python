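"""ICC estimation, permutation inference, and the derived statistics."""

import numpy as np
import pytest

from oracles import icc_oracle
from replistool import (OneWayICC, abundance_icc_trend,
                        generate_gaussian_replicates, icc_difference_test,
                        icc_oneway, icc_permutation_pvalue, phylum_media_ttest,
                        temporal_icc)


class TestOneWayICC:
    def test_zero_within_variance_gives_one(self):
        res = icc_oneway([("g1", [1, 1]), ("g2", [5, 5])])
        assert res.icc == pytest.approx(1.0)

    def test_hand_anova_example(self):
        res = icc_oneway([("g1", [1, 2]), ("g2", [3, 4])])
        assert res.msb == pytest.approx(4.0)
        assert res.msw == pytest.approx(0.5)
        assert res.icc == pytest.approx(3.5 / 4.5)
        assert res.sigma_e2_hat == pytest.approx(0.5)
        assert res.sigma_b2_hat == pytest.approx(1.75)

    def test_all_identical_is_degenerate_one(self):
        res = icc_oneway([("g1", [2, 2]), ("g2", [2, 2])])
        assert res.icc == 1.0
        assert res.degenerate

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="no values"):
            icc_oneway([("g1", []), ("g2", [1, 2])])

    def test_single_group_raises(self):
        with pytest.raises(ValueError, match="2 groups"):
            icc_oneway([("g1", [1, 2, 3])])

    def test_location_scale_invariance(self, rng):
        groups = [(f"g{i}", list(rng.normal(i, 1, 4))) for i in range(5)]
        base = icc_oneway(groups).icc
        shifted = [(g, [v + 100 for v in vals]) for g, vals in groups]
        scaled = [(g, [v * 3.7 for v in vals]) for g, vals in groups]
        assert icc_oneway(shifted).icc == pytest.approx(base, abs=1e-10)
        assert icc_oneway(scaled).icc == pytest.approx(base, abs=1e-10)

    def test_matches_brute_force_on_random_unbalanced_data(self, rng):
        for _ in range(20):
            n_groups = int(rng.integers(2, 7))
            groups = []
            for i in range(n_groups):
                k = int(rng.integers(1, 5))
                groups.append((f"g{i}", list(rng.normal(0, 1, k))))
            if sum(len(v) for _, v in groups) - n_groups < 1:
                continue
            res = icc_oneway(groups)
            icc, msb, msw, k_eff = icc_oracle(groups)
            assert res.icc == pytest.approx(icc, abs=1e-12)
            assert res.msb == pytest.approx(msb, abs=1e-12)
            assert res.msw == pytest.approx(msw, abs=1e-12)
            assert res.k_effective == pytest.approx(k_eff, abs=1e-12)

    def test_from_dataframe_constructor(self):
        import pandas as pd
        df = pd.DataFrame({"value": [1.0, 2.0, 3.0, 4.0],
                           "subject": ["a", "a", "b", "b"]})
        res = OneWayICC.from_dataframe(df, "value", "subject").fit()
        assert res.icc == pytest.approx(3.5 / 4.5)

    def test_summary_mentions_components(self):
        res = icc_oneway([("g1", [1, 2]), ("g2", [3, 4])])
        res.permutation_test(n_perm=99, seed=0)
        text = res.summary()
        assert "sigma_b^2" in text and "P (permutation)" in text

    @pytest.mark.parametrize("sb2, se2, expected", [(4, 1, 0.8), (1, 1, 0.5)])
    def test_recovers_true_icc_in_simulation(self, sb2, se2, expected):
        estimates = [icc_oneway(generate_gaussian_replicates(
            10, 3, sb2, se2, seed=s)).icc for s in range(200)]
        assert np.mean(estimates) == pytest.approx(expected, abs=0.06)


class TestPermutationInference:
    def test_perfect_separation_gives_minimal_p(self):
        groups = [(f"g{i}", [10 * i, 10 * i + 0.01, 10 * i - 0.01])
                  for i in range(8)]
        p = icc_permutation_pvalue(groups, n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_p_value_reproducible_given_seed(self):
        groups = generate_gaussian_replicates(6, 3, 1, 1, seed=9)
        p1 = icc_permutation_pvalue(groups, n_perm=199, seed=5)
        p2 = icc_permutation_pvalue(groups, n_perm=199, seed=5)
        assert p1 == p2

    def test_n_perm_too_small_raises(self):
        groups = generate_gaussian_replicates(4, 2, 1, 1, seed=0)
        with pytest.raises(ValueError):
            icc_permutation_pvalue(groups, n_perm=10, seed=0)

    def test_null_rejection_rate_near_alpha(self):
        # true ICC = 0: the test should be close to nominal level
        rejections = 0
        n_sims = 100
        for s in range(n_sims):
            groups = generate_gaussian_replicates(10, 3, 0.0, 1.0, seed=s)
            if icc_permutation_pvalue(groups, n_perm=199, seed=s) <= 0.05:
                rejections += 1
        assert 0.0 <= rejections / n_sims <= 0.11


class TestICCDifferenceTest:
    def test_identical_conditions_give_large_p(self):
        groups = generate_gaussian_replicates(8, 3, 2, 1, seed=3)
        p = icc_difference_test(groups, [(g, list(v)) for g, v in groups],
                                n_perm=199, seed=0)
        assert p == pytest.approx(1.0)

    def test_detects_large_reproducibility_difference(self):
        tight = generate_gaussian_replicates(10, 3, 4.0, 0.0001, seed=1)
        noisy = generate_gaussian_replicates(10, 3, 0.0, 4.0, seed=2)
        p = icc_difference_test(tight, noisy, n_perm=499, seed=0)
        assert p < 0.05

    def test_unmatched_subjects_warned_and_dropped(self):
        a = generate_gaussian_replicates(5, 3, 1, 1, seed=4)
        b = generate_gaussian_replicates(6, 3, 1, 1, seed=5)
        with pytest.warns(UserWarning, match="excluded"):
            p = icc_difference_test(a, b, n_perm=199, seed=0)
        assert 0 < p <= 1

    def test_type_i_error_near_alpha(self):
        rejections = 0
        n_sims = 60
        for s in range(n_sims):
            a = generate_gaussian_replicates(10, 3, 2, 1, seed=1000 + s)
            b = generate_gaussian_replicates(10, 3, 2, 1, seed=5000 + s)
            if icc_difference_test(a, b, n_perm=199, seed=s) <= 0.05:
                rejections += 1
        assert rejections / n_sims <= 0.13


class TestTemporalICC:
    def test_identical_times_give_one(self):
        vals = {"s1": 1.0, "s2": 3.0, "s3": 7.0}
        res = temporal_icc(vals, dict(vals))
        assert res.icc == pytest.approx(1.0)

    def test_two_subject_hand_example(self):
        res = temporal_icc({"a": 1.0, "b": 3.0}, {"a": 1.0, "b": 3.0})
        assert res.icc == pytest.approx(1.0)
        assert res.n_groups == 2

    def test_no_subject_signal_gives_near_zero(self):
        rng = np.random.default_rng(0)
        estimates = []
        for _ in range(300):
            t = {f"s{i}": rng.normal() for i in range(10)}
            z = {f"s{i}": rng.normal() for i in range(10)}
            estimates.append(temporal_icc(t, z).icc)
        assert abs(np.mean(estimates)) < 0.06

    def test_missing_subject_warned(self):
        with pytest.warns(UserWarning, match="excluded"):
            res = temporal_icc({"a": 1, "b": 2, "c": 9},
                               {"a": 1.1, "b": 2.2})
        assert res.n_groups == 2


class TestPhylumMediaTTest:
    def test_identical_vectors_degenerate(self):
        t, p = phylum_media_ttest([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert (t, p) == (0.0, 1.0)

    def test_constant_shift_extreme(self):
        t, p = phylum_media_ttest([1.0, 1.1, 1.2, 1.3],
                                  [0.0, 0.1, 0.2, 0.3])
        assert p == 0.0 and np.isinf(t)

    def test_hand_computed_paired_statistic(self):
        a, b = [0.1, 0.2, 0.15], [0.3, 0.5, 0.4]
        d = np.array(a) - np.array(b)
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        t, p = phylum_media_ttest(a, b)
        assert t == pytest.approx(expected_t, abs=1e-12)
        assert 0 < p < 1

    def test_too_few_subjects_raise(self):
        with pytest.raises(ValueError):
            phylum_media_ttest([0.1, 0.2], [0.2, 0.3])


class TestAbundanceICCTrend:
    def test_noiseless_linear_relation_recovered(self):
        abund = {f"t{i}": 10 ** (-i / 3) for i in range(12)}
        iccs = {t: 0.9 + 0.02 * np.log(a) for t, a in abund.items()}
        res = abundance_icc_trend(iccs, abund, floor=0.0)
        assert res.slope == pytest.approx(0.02, abs=1e-9)
        assert res.p_value < 1e-10

    def test_floor_excludes_below_threshold(self):
        abund = {"keep1": 0.0011, "keep2": 0.5, "keep3": 0.01,
                 "drop": 0.0009}
        iccs = {t: 0.9 for t in abund}
        res = abundance_icc_trend(iccs, abund)  # default floor 0.001
        assert res.n_taxa == 3

    def test_too_few_taxa_raise(self):
        with pytest.raises(ValueError, match="at least 3"):
            abundance_icc_trend({"a": 0.9, "b": 0.8},
                                {"a": 0.5, "b": 0.5})

    def test_null_slope_near_zero(self, rng):
        slopes = []
        for _ in range(100):
            abund = {f"t{i}": float(10 ** rng.uniform(-3, -0.5))
                     for i in range(30)}
            iccs = {t: float(rng.uniform(0.5, 1.0)) for t in abund}
            slopes.append(abundance_icc_trend(iccs, abund, floor=0.0).slope)
        assert abs(np.mean(slopes)) < 0.02
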