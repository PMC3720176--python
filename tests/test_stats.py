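"""Similarity scoring and the nonparametric comparison chain."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from gaitsemg import (
    bonferroni,
    compare_conditions,
    friedman,
    interpret_correlation,
    mann_whitney_u,
    shapiro_wilk,
    simulate_phase_amplitudes,
    spearman_similarity,
    wilcoxon_signed_rank,
)
from gaitsemg.stats import DegenerateDataError


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def brute_force_signed_rank_p(a, b):
    """Two-sided exact p over all 2^n sign assignments of |differences|."""
    d = a - b
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    hits = 0
    for signs in itertools.product((1, -1), repeat=d.size):
        s = np.asarray(signs)
        w = min(ranks[s > 0].sum(), ranks[s < 0].sum())
        if w <= w_obs + 1e-9:
            hits += 1
    return hits / 2 ** d.size


def brute_force_mwu_p(a, b):
    """Two-sided exact p over all C(n, n_a) group assignments (no ties)."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n_a, n_b = len(a), len(b)

    def u_min(rank_sum_a):
        u1 = rank_sum_a - n_a * (n_a + 1) / 2
        return min(u1, n_a * n_b - u1)

    u_obs = u_min(ranks[:n_a].sum())
    hits = sum(
        u_min(ranks[list(combo)].sum()) <= u_obs + 1e-9
        for combo in itertools.combinations(range(n_a + n_b), n_a)
    )
    from math import comb

    return hits / comb(n_a + n_b, n_a)


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------


class TestSpearman:
    def test_identity_is_one(self):
        a = np.arange(10.0)
        assert spearman_similarity(a, a).rho == pytest.approx(1.0)

    def test_reversal_is_minus_one(self):
        a = np.arange(10.0)
        res = spearman_similarity(a, a[::-1])
        assert res.rho == pytest.approx(-1.0)
        assert res.sign == "-"

    def test_tied_example_matches_hand_ranks(self):
        # ranks of a: [1, 2.5, 2.5, 4]; ranks of b: [2, 1, 3.5, 3.5];
        # Pearson of those rank vectors is 0.5
        res = spearman_similarity([1, 2, 2, 5], [3, 1, 4, 4])
        assert res.rho == pytest.approx(0.5)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateDataError):
            spearman_similarity([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 2**16))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=20)
        b = rng.normal(size=20)
        base = spearman_similarity(a, b).rho
        warped = spearman_similarity(np.exp(a), b**3).rho
        assert warped == pytest.approx(base, abs=1e-12)


class TestInterpretationScale:
    @pytest.mark.parametrize(
        "rho, label, sign",
        [
            (0.91, "very good to excellent", "+"),
            (0.52, "moderate", "+"),
            (-0.97, "very good to excellent", "-"),
            (0.0, "poor", "+"),
            (0.3, "fair", "+"),
            (0.7, "good", "+"),
            (1.0, "very good to excellent", "+"),
            (-1.0, "very good to excellent", "-"),
        ],
    )
    def test_published_scale(self, rho, label, sign):
        assert interpret_correlation(rho) == (label, sign)

    def test_total_and_monotone_in_magnitude(self):
        order = ["poor", "fair", "moderate", "good", "very good to excellent"]
        grid = np.linspace(0, 1, 2001)
        labels = [interpret_correlation(r)[0] for r in grid]
        indices = [order.index(lb) for lb in labels]
        assert np.all(np.diff(indices) >= 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            interpret_correlation(1.2)


class TestShapiroWilk:
    def test_type_one_calibration_under_normality(self):
        rng = np.random.default_rng(4)
        ps = [shapiro_wilk(rng.normal(size=30)).p_raw for _ in range(400)]
        assert abs(np.mean(np.asarray(ps) < 0.05) - 0.05) < 0.03

    def test_power_against_skew(self):
        rng = np.random.default_rng(5)
        rejections = np.mean(
            [shapiro_wilk(rng.exponential(size=20)).p_raw < 0.05
             for _ in range(200)]
        )
        assert rejections > 0.5

    def test_constant_sample_rejected(self):
        with pytest.raises(DegenerateDataError):
            shapiro_wilk(np.ones(10))

    def test_sample_size_bounds(self):
        with pytest.raises(ValueError):
            shapiro_wilk(np.arange(2.0))


class TestFriedman:
    def test_maximal_statistic_for_unanimous_ranking(self):
        x = np.tile([1.0, 2.0, 3.0], (9, 1)) + np.arange(9)[:, None] * 10
        assert friedman(x).statistic == pytest.approx(18.0)

    def test_identical_columns_null(self):
        x = np.tile(np.arange(5.0)[:, None], (1, 3))
        res = friedman(x)
        assert res.statistic == 0.0 and res.p_raw == 1.0

    def test_matches_scipy_on_random_data(self, rng):
        for _ in range(10):
            x = rng.normal(size=(7, 3))
            mine = friedman(x)
            ref = sps.friedmanchisquare(*x.T)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p_raw == pytest.approx(ref.pvalue, abs=1e-12)

    def test_chi_square_approximation_near_exact_permutation_p(self):
        """At n=5 blocks the chi2 p tracks the exact permutation p (all
        (3!)^5 within-block assignments) within 0.05 throughout the
        decision-relevant region (exact p <= 0.2). Mid-range p-values are
        known to deviate more; decisions at alpha = 0.05 are unaffected."""
        rng = np.random.default_rng(6)
        x = rng.normal(size=(5, 3))
        perms = list(itertools.permutations(range(3)))
        qs = np.array([
            friedman(np.stack([row[list(p)] for row, p in zip(x, assignment)]
                              )).statistic
            for assignment in itertools.product(perms, repeat=5)
        ])
        for q in np.unique(qs):
            exact_p = float(np.mean(qs >= q - 1e-9))
            if exact_p <= 0.2:
                approx_p = float(sps.chi2.sf(q, 2))
                assert abs(approx_p - exact_p) < 0.05

    def test_missing_cells_rejected(self):
        x = np.ones((4, 3))
        x[1, 2] = np.nan
        with pytest.raises(ValueError):
            friedman(x)


class TestWilcoxon:
    def test_identical_pairs_degenerate(self):
        with pytest.raises(DegenerateDataError):
            wilcoxon_signed_rank(np.arange(5.0), np.arange(5.0))

    def test_smallest_attainable_p_at_n5(self):
        # all five differences positive, no ties: p = 2 / 2^5
        res = wilcoxon_signed_rank(np.array([2.0, 3, 4, 5, 6]),
                                   np.array([1.0, 2, 3, 4, 5]) - [0, 1, 2, 3, 4])
        assert res.exact and res.statistic == 0.0
        assert res.p_raw == pytest.approx(0.0625, abs=1e-15)

    def test_exact_p_equals_enumeration_oracle(self, rng):
        for trial in range(15):
            n = int(rng.integers(4, 10))
            if trial % 2:  # integer data forces tied |differences|
                a = rng.integers(0, 5, n).astype(float)
                b = rng.integers(0, 5, n).astype(float)
            else:
                a, b = rng.normal(size=n), rng.normal(size=n)
            if np.all(a == b):
                continue
            res = wilcoxon_signed_rank(a, b)
            assert res.p_raw == pytest.approx(brute_force_signed_rank_p(a, b),
                                              abs=1e-12)

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(10):
            a, b = rng.normal(size=8), rng.normal(size=8)
            res = wilcoxon_signed_rank(a, b)
            ref = sps.wilcoxon(a, b, mode="exact")
            assert res.p_raw == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_large_n_uses_normal_approximation(self, rng):
        a, b = rng.normal(size=60), rng.normal(0.4, 1.0, size=60)
        res = wilcoxon_signed_rank(a, b)
        ref = sps.wilcoxon(a, b, correction=False, mode="approx")
        assert not res.exact
        assert res.p_raw == pytest.approx(float(ref.pvalue), rel=1e-9)


class TestMannWhitney:
    def test_complete_separation_4v4(self):
        res = mann_whitney_u(np.array([1.0, 2, 3, 4]), np.array([5.0, 6, 7, 8]))
        assert res.exact and res.statistic == 0.0
        assert res.p_raw == pytest.approx(2 / 70, abs=1e-15)

    def test_identical_groups_u_is_half_product(self):
        a = np.arange(6.0)
        res = mann_whitney_u(a, a + 0.5)
        assert res.statistic <= 6 * 6 / 2

    def test_exact_p_equals_enumeration_oracle(self, rng):
        for _ in range(3):
            a = rng.normal(size=6)
            b = rng.normal(0.8, 1.0, size=5)
            res = mann_whitney_u(a, b)
            assert res.exact
            assert res.p_raw == pytest.approx(brute_force_mwu_p(a, b), abs=1e-12)

    def test_ties_fall_back_to_corrected_normal(self):
        a = np.array([1.0, 2.0, 2.0, 3.0])
        b = np.array([2.0, 3.0, 4.0, 4.0])
        res = mann_whitney_u(a, b)
        assert not res.exact
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.p_raw == pytest.approx(float(ref.pvalue), rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u(np.array([]), np.array([1.0]))


class TestBonferroni:
    def test_triples_p_for_three_comparisons(self):
        assert bonferroni([0.004], m=3)[0] == pytest.approx(0.012)

    def test_caps_at_one(self):
        assert bonferroni([0.5], m=3)[0] == 1.0

    def test_identity_for_single_comparison(self):
        assert bonferroni([0.3], m=1)[0] == pytest.approx(0.3)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2], m=3)


class TestCompareConditions:
    def test_identical_columns_no_flags(self):
        x = np.tile(np.arange(9.0)[:, None], (1, 3))
        omnibus, pairwise, pairs, flags = compare_conditions(x)
        assert omnibus.p_raw == 1.0
        assert not any(flags)
        assert all(r.p_adjusted == 1.0 for r in pairwise)
        assert len(pairs) == 3

    def test_adjusted_p_at_least_raw(self, rng):
        x = rng.normal(5.0, 1.0, (9, 3))
        _, pairwise, _, _ = compare_conditions(x)
        assert all(r.p_adjusted >= r.p_raw for r in pairwise)

    def test_detects_therapist_gain_effect(self):
        """Smoke-level power check: 1.5x encouragement gain at n=9 flags the
        DGO vs DGO+therapist pair in most replicates."""
        gains = {"DGO": 1.0, "DGO_therapist": 1.5, "treadmill": 1.3}
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(40):
            amps, conds = simulate_phase_amplitudes(9, gains, rng)
            _, _, pairs, flags = compare_conditions(amps, condition_labels=tuple(conds))
            hits += flags[pairs.index(("DGO", "DGO_therapist"))]
        assert hits / 40 >= 0.7

    def test_null_flag_rate_controlled(self):
        gains = {"DGO": 1.0, "DGO_therapist": 1.0, "treadmill": 1.0}
        rng = np.random.default_rng(10)
        flags_per_pair = np.zeros(3)
        reps = 300
        for _ in range(reps):
            amps, conds = simulate_phase_amplitudes(9, gains, rng)
            _, _, _, flags = compare_conditions(amps, condition_labels=tuple(conds))
            flags_per_pair += flags
        assert np.all(flags_per_pair / reps <= 0.05 + 0.03)
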