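"""Unit and property tests for the missingness statistics and quantile scan."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polystest import ComparisonSpec, binom_missing, diff_probabilities, miss_test, scenario_scan
from polystest.simulate import SimulationParams, generate_dataset

from conftest import make_matrix


def enumerate_diff_distribution(r, p_na):
    """Oracle: walk all 2^(2r) missingness patterns, weight by p_na, tally |k_a - k_b|."""
    P = np.zeros(r + 1)
    for pattern in itertools.product([0, 1], repeat=2 * r):
        n_miss = sum(pattern)
        weight = p_na**n_miss * (1 - p_na) ** (2 * r - n_miss)
        k = abs(sum(pattern[:r]) - sum(pattern[r:]))
        P[k] += weight
    return P


class TestBinomMissing:
    def test_closed_form_r3_half(self):
        np.testing.assert_allclose(binom_missing(3, 0.5), [1 / 8, 3 / 8, 3 / 8, 1 / 8])

    def test_degenerate_no_missingness(self):
        np.testing.assert_array_equal(binom_missing(3, 0.0), [1, 0, 0, 0])

    def test_matches_weighted_pattern_enumeration(self):
        b = binom_missing(5, 0.2)
        oracle = np.zeros(6)
        for pattern in itertools.product([0, 1], repeat=5):
            k = sum(pattern)
            oracle[k] += 0.2**k * 0.8 ** (5 - k)
        np.testing.assert_allclose(b, oracle, atol=1e-14)
        assert b.sum() == pytest.approx(1.0)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            binom_missing(3, 1.5)


class TestDiffProbabilities:
    def test_worked_example_r3_half(self):
        table = diff_probabilities(3, 0.5)
        np.testing.assert_allclose(table.P, [5 / 16, 15 / 32, 3 / 16, 1 / 32])

    def test_no_missingness_concentrates_at_zero(self):
        table = diff_probabilities(3, 0.0)
        np.testing.assert_array_equal(table.P, [1, 0, 0, 0])

    def test_r2_half_enumeration(self):
        np.testing.assert_allclose(diff_probabilities(2, 0.5).P, [3 / 8, 1 / 2, 1 / 8])

    @pytest.mark.parametrize("r", [1, 2, 3, 4, 5])
    @pytest.mark.parametrize("p_na", [0.1, 0.3, 0.5, 0.7, 0.9])
    def test_equals_pattern_enumeration(self, r, p_na):
        table = diff_probabilities(r, p_na)
        np.testing.assert_allclose(table.P, enumerate_diff_distribution(r, p_na), atol=1e-13)
        assert table.P.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unequal_replicates_reduce_to_equal_case(self):
        np.testing.assert_allclose(
            diff_probabilities(4, 0.3, r_b=4).P, diff_probabilities(4, 0.3).P
        )

    def test_unequal_replicates_match_enumeration(self):
        r_a, r_b, p = 3, 2, 0.4
        oracle = np.zeros(max(r_a, r_b) + 1)
        for pa in itertools.product([0, 1], repeat=r_a):
            for pb in itertools.product([0, 1], repeat=r_b):
                n = sum(pa) + sum(pb)
                w = p**n * (1 - p) ** (r_a + r_b - n)
                oracle[abs(sum(pa) - sum(pb))] += w
        np.testing.assert_allclose(diff_probabilities(r_a, p, r_b=r_b).P, oracle, atol=1e-13)


class TestScenarioScan:
    def test_complete_matrix_first_scenario_has_no_missingness(self):
        m = make_matrix(np.arange(24.0).reshape(6, 4) + 1)
        scans = scenario_scan(m, [ComparisonSpec("A", "B")], n_quantiles=10)
        assert scans[0].p_na == 0.0
        assert len(scans) == 10

    def test_threshold_above_feature_forces_k_zero(self):
        # feature 1 low everywhere: once censored in both groups, k = 0
        vals = [[0.0, 0.1, 10.0, 10.1], [20.0, 21.0, 30.0, 31.0]]
        m = make_matrix(vals)
        c = ComparisonSpec("A", "B")
        scans = scenario_scan(m, [c], n_quantiles=8)
        top = scans[-1]
        assert top.threshold > 10.1
        assert top.diff_counts[c.key][0] == 0

    def test_p_na_matches_brute_force_recount(self):
        rng = np.random.default_rng(4)
        vals = rng.standard_normal((4, 6))
        vals[0, 1] = np.nan
        m = make_matrix(vals)
        c = ComparisonSpec("A", "B")
        scans = scenario_scan(m, [c], n_quantiles=12)
        obs = vals[np.isfinite(vals)]
        for q, s in enumerate(scans):
            t = np.quantile(obs, q / 12)
            masked = vals.copy()
            masked[np.isfinite(masked) & (masked < t)] = np.nan
            assert s.p_na == pytest.approx(np.isnan(masked).mean())
            ka = np.isnan(masked[:, :3]).sum(axis=1)
            kb = np.isnan(masked[:, 3:]).sum(axis=1)
            np.testing.assert_array_equal(s.diff_counts[c.key], np.abs(ka - kb))

    def test_all_missing_matrix_rejected(self):
        with pytest.raises(ValueError, match="no observed"):
            scenario_scan(make_matrix(np.full((2, 4), np.nan)), [ComparisonSpec("A", "B")])


def naive_miss_test(m, c, n_quantiles=100):
    """Independent loop-based re-implementation used as an oracle."""
    vals = m.values
    obs = vals[np.isfinite(vals)]
    thresholds = [np.quantile(obs, q / n_quantiles) for q in range(n_quantiles)]
    ia = m.column_indices(c.condition_a)
    ib = m.column_indices(c.condition_b)
    r = len(ia)
    best = np.full(vals.shape[0], np.inf)
    for t in thresholds:
        masked = np.where(np.isfinite(vals) & (vals < t), np.nan, vals)
        p_na = np.isnan(masked).sum() / masked.size
        b = [math.comb(r, i) * p_na**i * (1 - p_na) ** (r - i) for i in range(r + 1)]
        P = [sum(x * x for x in b)] + [
            2 * sum(b[j + k] * b[j] for j in range(r - k + 1)) for k in range(1, r + 1)
        ]
        for f in range(vals.shape[0]):
            k = abs(
                int(np.isnan(masked[f, ia]).sum()) - int(np.isnan(masked[f, ib]).sum())
            )
            best[f] = min(best[f], P[k])
    return np.minimum(best * (r + 1), 1.0)


class TestMissTest:
    def test_all_missing_versus_fully_observed_hits_one_thirtysecond(self):
        # engineered so the matrix-wide missing fraction is exactly 1/2 at r=3
        nan = np.nan
        vals = [
            [nan, nan, nan, 5.0, 5.1, 5.2],
            [nan, nan, nan, 1.0, 1.1, 1.2],
            [2.0, 2.1, 2.2, nan, nan, nan],
            [3.0, 3.1, 3.2, nan, nan, nan],
        ]
        m = make_matrix(vals)
        scans = scenario_scan(m, [ComparisonSpec("A", "B")], n_quantiles=100)
        assert scans[0].p_na == 0.5
        table = diff_probabilities(3, 0.5)
        assert table.P[3] == pytest.approx(1 / 32)
        p = miss_test(m, ComparisonSpec("A", "B"))
        # the uncensored scenario alone already contributes P_3 * (r+1) = 1/8
        assert (p <= 4 * (1 / 32) + 1e-12).all()

    def test_identical_fully_observed_groups_follow_forced_k_zero_path(self):
        base = np.linspace(1, 2, 4)
        vals = np.column_stack([base] * 6)
        m = make_matrix(vals)
        p = miss_test(m, ComparisonSpec("A", "B"), n_quantiles=4)
        scans = scenario_scan(m, [ComparisonSpec("A", "B")], n_quantiles=4)
        expected = min(diff_probabilities(3, s.p_na).P[0] for s in scans)
        np.testing.assert_allclose(p, min(1.0, 4 * expected))

    def test_matches_naive_loop_oracle(self, toy_matrix, ab_comparison):
        fast = miss_test(toy_matrix, ab_comparison, n_quantiles=25)
        slow = naive_miss_test(toy_matrix, ab_comparison, n_quantiles=25)
        np.testing.assert_allclose(fast, slow, atol=1e-12)

    def test_invariant_under_feature_reorder_and_global_shift(self, toy_matrix, ab_comparison):
        p = miss_test(toy_matrix, ab_comparison)
        shifted = toy_matrix.with_values(toy_matrix.values + 7.5)
        np.testing.assert_allclose(miss_test(shifted, ab_comparison), p, atol=1e-12)
        order = [3, 0, 5, 1, 4, 2]
        reordered = make_matrix(
            toy_matrix.values[order], feature_ids=[toy_matrix.feature_ids[i] for i in order]
        )
        np.testing.assert_allclose(miss_test(reordered, ab_comparison), p[order], atol=1e-12)

    def test_raising_group_b_never_hurts_significance(self, toy_matrix, ab_comparison):
        p_before = miss_test(toy_matrix, ab_comparison)
        vals = toy_matrix.values.copy()
        vals[0, 3:] += 50.0  # keeps feature 0's B values above every scan threshold
        p_after = miss_test(toy_matrix.with_values(vals), ab_comparison)
        assert p_after[0] <= p_before[0] + 1e-12

    def test_null_small_p_tail_is_valid(self):
        """Under a global null the small-p tail must not exceed its nominal level.

        The full distribution is intentionally conservative (mass at p = 1
        from the cap), so validity is asserted as a sub-uniform ECDF rather
        than global uniformity.
        """
        m, _ = generate_dataset(
            SimulationParams(
                n_features=2000, n_replicates=5, frac_regulated=0.0,
                frac_missing=20.0, mu=1.0, seed=11,
            )
        )
        p = miss_test(m, ComparisonSpec("A", "B"))
        n = p.size
        for alpha in (0.001, 0.01, 0.05, 0.1):
            se = np.sqrt(alpha * (1 - alpha) / n)
            assert np.mean(p <= alpha) <= alpha + 3 * se
        grid = np.linspace(0.001, 1.0, 200)
        ecdf = np.searchsorted(np.sort(p), grid, side="right") / n
        assert np.max(ecdf - grid) <= 3 * np.sqrt(0.25 / n)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    r=st.integers(min_value=1, max_value=5),
    p_na=st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
)
def test_diff_probabilities_is_a_distribution(r, p_na):
    P = diff_probabilities(r, p_na).P
    assert (P >= -1e-15).all() and (P <= 1 + 1e-12).all()
    assert P.sum() == pytest.approx(1.0, abs=1e-10)
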