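"""Exact tests, BH correction, beta uncertainty, stratified and rank tests.

The Fisher implementation is cross-checked two independent ways: against an
exact integer-arithmetic enumeration oracle (random margins here; the full
exhaustive sweep lives in the acceptance suite) and against
scipy.stats.fisher_exact.
"""

import math
from bisect import bisect_right
from itertools import accumulate
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from tamuc.stats import (
    ContingencyTable,
    FrequencyEstimate,
    beta_sd,
    bh_adjust,
    cooccurrence,
    fisher_2x2,
    fisher_pvalues_all_tables,
    fisher_rxc_enumerate,
    fisher_rxc_mc,
    pearson_corr,
    rank_sum,
    shift_compare,
    stratified_fisher,
)

TEN7 = 10**7


def oracle_fisher_pvalues(n1: int, n2: int, m: int) -> np.ndarray:
    """Two-sided Fisher P for every allocation, by exact integer enumeration.

    Point probabilities are proportional to the integer weights
    C(n1,a)*C(n2,m-a); the probability-mass rule (with the same 1e-7 tie
    tolerance as the implementation) is evaluated in exact arithmetic.
    """
    lo, hi = max(0, m - n2), min(m, n1)
    ws = [comb(n1, a) * comb(n2, m - a) for a in range(lo, hi + 1)]
    total = sum(ws)
    sw = sorted(ws)
    cums = list(accumulate(sw))
    out = []
    for w in ws:
        bound = w * (TEN7 + 1)
        j = bisect_right([v * TEN7 for v in sw], bound)
        out.append(cums[j - 1] / total)
    return np.array(out)


class TestFisher2x2:
    def test_reconstructed_discovery_table(self):
        # 14% vs 48% mutation frequency at n = 21 vs 554
        res = fisher_2x2([[3, 18], [266, 288]])
        assert res.p_value == pytest.approx(0.003, abs=5e-4)

    def test_equal_proportions(self):
        # two-sided P is exactly 1 for identical proportions; the one-sided
        # tails are symmetric and equal (1 + P(X = a)) / 2
        assert fisher_2x2([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)
        less = fisher_2x2([[5, 5], [5, 5]], "less").p_value
        greater = fisher_2x2([[5, 5], [5, 5]], "greater").p_value
        assert less == pytest.approx(greater)
        assert less == pytest.approx(
            sps.fisher_exact([[5, 5], [5, 5]], alternative="less").pvalue
        )

    def test_hand_enumerated_table(self):
        # all C(20,10)=184756 fixed-margin tables; 202 have point prob <=
        # the observed one
        res = fisher_2x2([[1, 9], [9, 1]])
        assert res.p_value == pytest.approx(202 / 184756, rel=1e-10)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            fisher_2x2([[1, -1], [2, 3]])

    def test_odds_ratio_conventions(self):
        assert fisher_2x2([[0, 10], [5, 5]]).odds_ratio == 0.0
        assert fisher_2x2([[5, 0], [5, 5]]).odds_ratio == math.inf
        assert fisher_2x2([[2, 4], [4, 2]]).odds_ratio == pytest.approx(0.25)

    @given(
        a=st.integers(0, 15), b=st.integers(0, 15),
        c=st.integers(0, 15), d=st.integers(0, 15),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_integer_oracle(self, a, b, c, d):
        n1, n2, m = a + b, c + d, a + c
        if n1 == 0 or n2 == 0:
            return
        support, impl = fisher_pvalues_all_tables(n1, n2, m)
        orc = oracle_fisher_pvalues(n1, n2, m)
        np.testing.assert_allclose(impl, orc, rtol=1e-9)
        assert fisher_2x2([[a, b], [c, d]]).p_value == pytest.approx(
            orc[a - support[0]], rel=1e-9
        )

    @given(
        a=st.integers(0, 25), b=st.integers(0, 25),
        c=st.integers(0, 25), d=st.integers(0, 25),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_scipy_all_sidedness(self, a, b, c, d):
        if a + b == 0 or c + d == 0:
            return
        table = [[a, b], [c, d]]
        for side, alt in (("two_sided", "two-sided"), ("less", "less"),
                          ("greater", "greater")):
            ours = fisher_2x2(table, side).p_value
            ref = sps.fisher_exact(table, alternative=alt).pvalue
            assert ours == pytest.approx(ref, rel=1e-9)


class TestFisherRxcMc:
    def test_degenerate_single_row_p_one(self):
        res = fisher_rxc_mc([[5, 3, 2], [0, 0, 0]], iterations=1000, seed=0)
        assert res.p_value == 1.0

    def test_converges_to_enumeration(self):
        table = [[5, 0, 0], [0, 5, 5]]
        exact = fisher_rxc_enumerate(table)
        res = fisher_rxc_mc(table, iterations=200_000, seed=5)
        assert abs(res.p_value - exact) <= 4 * res.mc_se + 1e-5

    def test_random_small_tables_vs_enumeration(self, rng):
        for _ in range(3):
            table = rng.integers(0, 4, size=(3, 3))
            table[0, 0] += 1  # avoid fully degenerate margins
            exact = fisher_rxc_enumerate(table)
            res = fisher_rxc_mc(table, iterations=100_000, seed=9)
            assert abs(res.p_value - exact) <= 4 * res.mc_se + 1e-4

    def test_seed_reproducible(self):
        t = [[4, 1, 0], [1, 3, 4]]
        p1 = fisher_rxc_mc(t, iterations=10_000, seed=42).p_value
        p2 = fisher_rxc_mc(t, iterations=10_000, seed=42).p_value
        assert p1 == p2

    def test_2x2_delegates_to_exact(self):
        res = fisher_rxc_mc([[3, 18], [266, 288]], iterations=100, seed=0)
        assert res.method == "fisher_exact"
        assert res.p_value == pytest.approx(fisher_2x2([[3, 18], [266, 288]]).p_value)


class TestBhAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        q = bh_adjust([0.0009, 0.003, 0.5, 0.7, 0.9])
        assert q[0] == pytest.approx(0.0045)
        assert q[1] == pytest.approx(0.0075)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_q_dominates_p_and_is_monotone(self, ps):
        q = bh_adjust(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        assert np.all(q <= 1 + 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_permutation_equivariant(self, rng):
        ps = rng.uniform(size=12)
        perm = rng.permutation(12)
        np.testing.assert_allclose(bh_adjust(ps[perm]), bh_adjust(ps)[perm])


class TestBetaSd:
    def test_uniform_case(self):
        assert beta_sd(0, 0) == pytest.approx(math.sqrt(1 / 12))

    def test_closed_form_discovery_counts(self):
        # a=4, b=19: sqrt(76/(23^2 * 24))
        assert beta_sd(3, 21) == pytest.approx(math.sqrt(76 / 12696), rel=1e-12)

    @pytest.mark.parametrize("k,n", [(0, 5), (2, 7), (10, 30), (17, 21)])
    def test_symmetry_and_numeric_integration(self, k, n):
        assert beta_sd(k, n) == pytest.approx(beta_sd(n - k, n), rel=1e-12)
        assert beta_sd(k, n) == pytest.approx(
            sps.beta(k + 1, n - k + 1).std(), abs=1e-10
        )

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            beta_sd(5, 3)

    def test_frequency_estimate_wraps_it(self):
        est = FrequencyEstimate(3, 21)
        assert est.freq == pytest.approx(3 / 21)
        assert est.sd == pytest.approx(beta_sd(3, 21))
        assert (est.beta_a, est.beta_b) == (4, 19)


class TestStratifiedFisher:
    def test_single_stratum_reduces_to_fisher(self, rng):
        for _ in range(20):
            t = rng.integers(0, 8, size=(2, 2)) + 1
            for side in ("two_sided", "less", "greater"):
                combined = stratified_fisher([t], side).p_value
                plain = fisher_2x2(t, side).p_value
                assert combined == pytest.approx(plain, rel=1e-9)

    def test_two_diagonal_strata(self):
        # per-stratum pmf {1/6, 4/6, 1/6}; convolved mass at S in {0, 4} is
        # 2/36
        p = stratified_fisher([[[2, 0], [0, 2]], [[2, 0], [0, 2]]]).p_value
        assert p == pytest.approx(2 / 36, rel=1e-12)

    def test_zero_marginal_stratum_is_noop(self):
        base = [[[3, 1], [2, 4]], [[1, 5], [4, 2]]]
        with_empty = base + [[[0, 3], [0, 5]]]  # zero first-column margin
        for side in ("two_sided", "less", "greater"):
            assert stratified_fisher(with_empty, side).p_value == pytest.approx(
                stratified_fisher(base, side).p_value, rel=1e-12
            )

    def test_all_strata_excluded_errors(self):
        with pytest.raises(ValueError, match="no informative strata"):
            stratified_fisher([[[0, 0], [3, 4]]])

    def test_grade_confounding_recovered(self):
        # within each stratum the two groups share the same frequency
        # (0.8 and 0.1) but group 1 is drawn mostly from the high-rate
        # stratum: the pooled test is fooled, the stratified test is not
        strata = [np.array([[16, 4], [8, 2]]), np.array([[1, 9], [20, 180]])]
        pooled = strata[0] + strata[1]
        assert fisher_2x2(pooled).p_value < 0.001
        assert stratified_fisher(strata).p_value > 0.5


class TestCooccurrence:
    def test_identical_vectors_maximal_or(self):
        a = np.array([True] * 5 + [False] * 15)
        res = cooccurrence(a, a)
        assert res.odds_ratio == math.inf
        assert res.p_value < 0.01

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cooccurrence([True], [True, False])

    def test_null_calibration(self):
        rejections = 0
        n_sims = 400
        for seed in range(n_sims):
            r = np.random.default_rng(seed)
            a = r.uniform(size=80) < 0.3
            b = r.uniform(size=80) < 0.4
            if cooccurrence(a, b).p_value < 0.05:
                rejections += 1
        se = math.sqrt(0.05 * 0.95 / n_sims)
        assert rejections / n_sims <= 0.05 + 3 * se

    def test_planted_exclusivity_recovered(self):
        # exposure indicator (23 of 577) against an event with true OR 0.2
        p_control = 0.48
        odds_exp = 0.2 * p_control / (1 - p_control)
        p_exposed = odds_exp / (1 + odds_exp)
        below_one = 0
        n_seeds = 100
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            exposure = np.array([True] * 23 + [False] * 554)
            event = np.where(
                exposure, r.uniform(size=577) < p_exposed,
                r.uniform(size=577) < p_control,
            )
            res = cooccurrence(exposure, event)
            if res.odds_ratio < 1:
                below_one += 1
        assert below_one >= 95


class TestRankSum:
    def test_identical_samples_p_one(self):
        res = rank_sum([1, 2, 3, 4] * 3, [1, 2, 3, 4] * 3)
        assert res.method.endswith("asymptotic")
        assert res.p_value == pytest.approx(1.0)

    def test_tiny_exact_enumeration(self):
        res = rank_sum([1, 2], [3, 4], "less")
        assert res.method.endswith("exact")
        assert res.p_value == pytest.approx(1 / 6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rank_sum([], [1.0])

    def test_shift_invariance(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=25)
        assert rank_sum(x + 7, y + 7).p_value == pytest.approx(
            rank_sum(x, y).p_value
        )

    def test_reports_medians(self):
        res = rank_sum([1, 2, 3], [10, 20, 30, 40])
        assert res.extra["median_x"] == 2 and res.extra["median_y"] == 25


class TestShiftCompare:
    def test_zero_shift_is_rank_sum(self, rng):
        x, y = rng.poisson(2, 20), rng.poisson(2, 30)
        assert shift_compare(x, y, 0).p_value == pytest.approx(
            rank_sum(x, y).p_value
        )

    def test_exact_shift_equalises(self):
        res = shift_compare([1, 1], [2, 2], shift=1)
        assert res.p_value == pytest.approx(1.0)

    def test_negative_shift_rejected(self):
        with pytest.raises(ValueError):
            shift_compare([1], [2], shift=-1)


class TestPearson:
    def test_perfect_linear(self):
        res = pearson_corr([1, 2, 3, 4], [3, 5, 7, 9])
        assert res.statistic == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert pearson_corr([1, 2, 3], [-1, -2, -3]).statistic == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        x = np.array([1.0, 2.5, 3.0, 4.7, 5.1])
        y = np.array([2.2, 1.9, 3.8, 4.1, 4.0])
        r_manual = np.sum((x - x.mean()) * (y - y.mean())) / math.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert pearson_corr(x, y).statistic == pytest.approx(r_manual, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr([1, 1, 1], [1, 2, 3])


class TestContingencyTable:
    def test_rejects_negative_and_1d(self):
        with pytest.raises(ValueError):
            ContingencyTable(counts=np.array([[1, -2], [0, 3]]))
        with pytest.raises(ValueError):
            ContingencyTable(counts=np.array([1, 2, 3]))

    def test_labels_checked(self):
        with pytest.raises(ValueError):
            ContingencyTable(counts=np.eye(2, dtype=int), row_labels=("a",))
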