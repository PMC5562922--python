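"""AUC summarization, permutation inference, FDR, behavior correlations."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcnet.stats import (
    behavior_correlation,
    curve_auc,
    fdr_bh,
    permutation_group_test,
    permutation_group_test_matrix,
    two_sample_t_from_summary,
)


class TestCurveAuc:
    def test_constant_curve_is_interval_width(self):
        d = np.round(np.arange(0.245, 0.3005, 0.005), 10)
        assert curve_auc(np.ones(12), d) == pytest.approx(0.055)

    def test_linear_ramp(self):
        d = np.linspace(0, 1, 11)
        assert curve_auc(d, d) == pytest.approx(0.5)

    def test_matches_fine_grid_refinement(self, rng):
        d = np.round(np.arange(0.245, 0.3005, 0.005), 10)
        v = rng.standard_normal(12)
        fine = np.linspace(d[0], d[-1], 20001)
        oracle = np.trapezoid(np.interp(fine, d, v), fine)
        assert curve_auc(v, d) == pytest.approx(oracle, abs=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=12),
           st.floats(-5, 5), st.floats(-5, 5))
    def test_linearity(self, v, a, b):
        v = np.array(v)
        w = v[::-1].copy()
        d = np.linspace(0.1, 0.9, len(v))
        lhs = curve_auc(a * v + b * w, d)
        rhs = a * curve_auc(v, d) + b * curve_auc(w, d)
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            curve_auc([1, 2, 3], [0.1, 0.2])


class TestPermutationTest:
    def test_identical_groups_give_p_one(self):
        res = permutation_group_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                                     n_perm=500, rng=np.random.default_rng(0))
        assert res.observed_diff == 0.0
        assert res.p_two_tailed == 1.0

    def test_constant_values_warn_and_return_one(self):
        with pytest.warns(UserWarning, match="identical"):
            res = permutation_group_test([2.0, 2.0], [2.0, 2.0, 2.0], n_perm=500)
        assert res.p_two_tailed == 1.0

    def test_sampled_p_matches_exhaustive_enumeration(self):
        """a=(10..13), b=(0..3): enumeration of all C(8,4)=70 assignments
        gives p = 2/70; the sampled p lands within 3 binomial SEs."""
        a, b = [10.0, 11, 12, 13], [0.0, 1, 2, 3]
        pooled = np.array(a + b)
        obs = np.mean(a) - np.mean(b)
        count = sum(
            1
            for idx in combinations(range(8), 4)
            if abs(pooled[list(idx)].mean()
                   - np.delete(pooled, list(idx)).mean()) >= abs(obs) - 1e-12
        )
        p_exact = count / math.comb(8, 4)
        assert p_exact == pytest.approx(2 / 70)

        res = permutation_group_test(a, b, n_perm=10_000,
                                     rng=np.random.default_rng(4))
        se = math.sqrt(p_exact * (1 - p_exact) / 10_000)
        assert abs(res.p_two_tailed - p_exact) < 3 * se

        exact = permutation_group_test(a, b, exact=True)
        assert exact.p_two_tailed == pytest.approx(p_exact)

    def test_exact_mode_matches_enumeration_on_random_data(self, rng):
        a = rng.standard_normal(5)
        b = rng.standard_normal(4) + 0.8
        pooled = np.concatenate([a, b])
        obs = a.mean() - b.mean()
        count = sum(
            1
            for idx in combinations(range(9), 5)
            if abs(pooled[list(idx)].mean()
                   - np.delete(pooled, list(idx)).mean()) >= abs(obs) - 1e-12
        )
        res = permutation_group_test(a, b, exact=True)
        assert res.p_two_tailed == pytest.approx(count / math.comb(9, 5))

    def test_translation_invariance(self):
        a = [3.0, 4, 5, 9]
        b = [1.0, 2, 2.5, 6]
        p1 = permutation_group_test(a, b, n_perm=2000,
                                    rng=np.random.default_rng(7)).p_two_tailed
        p2 = permutation_group_test([x + 100 for x in a], [x + 100 for x in b],
                                    n_perm=2000,
                                    rng=np.random.default_rng(7)).p_two_tailed
        assert p1 == p2

    def test_matrix_version_agrees_with_scalar(self, rng):
        A = rng.standard_normal((8, 3))
        B = rng.standard_normal((6, 3)) + 0.5
        obs, p = permutation_group_test_matrix(A, B, n_perm=5000,
                                               rng=np.random.default_rng(13))
        for col in range(3):
            res = permutation_group_test(A[:, col], B[:, col], n_perm=5000,
                                         rng=np.random.default_rng(13))
            assert obs[col] == pytest.approx(res.observed_diff)
            assert p[col] == pytest.approx(res.p_two_tailed)

    def test_add_one_estimator_never_zero(self, rng):
        res = permutation_group_test(rng.normal(10, 1, 20), rng.normal(0, 1, 20),
                                     n_perm=200, rng=rng)
        assert res.p_two_tailed >= 1 / 201


class TestFdrBh:
    def test_all_tiny_all_significant(self):
        assert fdr_bh([0.001] * 90).all()

    def test_all_large_none_significant(self):
        assert not fdr_bh([0.9] * 90).any()

    def test_hand_step_up_example(self):
        """p=(.01,.02,.03,.5) at q=.05: p_(3)=.03 <= 3*.05/4 so the first
        three are kept."""
        mask = fdr_bh([0.01, 0.02, 0.03, 0.5], q=0.05)
        assert mask.tolist() == [True, True, True, False]

    def test_empty_input(self):
        assert fdr_bh([]).size == 0

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_brute_force_step_up(self, pvals):
        q = 0.05
        p = np.array(pvals)
        order = np.argsort(p, kind="stable")
        m = len(p)
        k_max = 0
        for rank, idx in enumerate(order, start=1):
            if p[idx] <= q * rank / m:
                k_max = rank
        oracle = np.zeros(m, dtype=bool)
        oracle[order[:k_max]] = True
        np.testing.assert_array_equal(fdr_bh(p, q), oracle)


class TestBehaviorCorrelation:
    def test_affine_relation_gives_r_one(self):
        x = np.arange(10.0)
        r, p = behavior_correlation(x, 3 * x + 2)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_null_calibration_at_n72(self):
        """With true rho=0 and n=72, |r| exceeds the p<0.05 bound (~0.232)
        in about 5% of replicates."""
        rng = np.random.default_rng(99)
        hits = 0
        reps = 2000
        for _ in range(reps):
            _, p = behavior_correlation(rng.standard_normal(72),
                                        rng.standard_normal(72))
            hits += p < 0.05
        assert 0.03 < hits / reps < 0.07

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            behavior_correlation([1.0, 1, 1, 1], [1.0, 2, 3, 4])

    def test_too_few_pairs_errors(self):
        with pytest.raises(ValueError, match="4 paired"):
            behavior_correlation([1.0, 2, 3], [1.0, 2, 3])


class TestSummaryTTest:
    def test_equal_means_give_zero(self):
        t, df = two_sample_t_from_summary(5, 1, 10, 5, 2, 12)
        assert t == 0.0 and df == 20

    def test_math_score_summaries(self):
        t, df = two_sample_t_from_summary(56.97, 8.01, 72, 48.16, 8.30, 72)
        assert df == 142
        assert t == pytest.approx(6.44, abs=0.05)

    def test_raven_summaries(self):
        t, df = two_sample_t_from_summary(107.94, 12.40, 72, 104.50, 13.65, 72)
        assert df == 142
        assert t == pytest.approx(1.57, abs=0.03)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            two_sample_t_from_summary(1, 0, 10, 2, 1, 10)
        with pytest.raises(ValueError):
            two_sample_t_from_summary(1, 1, 1, 2, 1, 10)
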