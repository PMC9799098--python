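"""Rank tests against exhaustive enumeration; chi-square and regression."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from calyxmorph.stats import (
    SummaryStat,
    bonferroni_alpha,
    chi_square,
    kruskal_wallis,
    pairwise_after_kruskal,
    tonotopic_regression,
    wilcoxon_rank_sum,
)


def midranks(values):
    """Plain-python midranks (oracle helper, independent of scipy)."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        r = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = r
        i = j + 1
    return ranks


def enumerate_ranksum_p(a, b):
    """Oracle: exact two-sided p by enumerating every subset assignment."""
    pooled = list(a) + list(b)
    ranks = midranks(pooled)
    n_a = len(a)
    w_obs = sum(ranks[:n_a])
    ws = [sum(ranks[i] for i in c)
          for c in itertools.combinations(range(len(pooled)), n_a)]
    lo = sum(w <= w_obs + 1e-9 for w in ws) / len(ws)
    hi = sum(w >= w_obs - 1e-9 for w in ws) / len(ws)
    return min(1.0, 2.0 * min(lo, hi))


class TestBonferroni:
    def test_published_alpha(self):
        assert bonferroni_alpha(0.05, 3) == 0.0167

    @pytest.mark.parametrize("alpha,m,expected", [
        (0.05, 1, 0.05), (0.01, 5, 0.002),
    ])
    def test_simple_cases(self, alpha, m, expected):
        assert bonferroni_alpha(alpha, m) == pytest.approx(expected)

    def test_zero_comparisons_errors(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestRankSum:
    def test_identical_samples_p_one(self):
        with pytest.warns(UserWarning):
            res = wilcoxon_rank_sum([2.0, 2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0

    def test_fully_separated_three_vs_three(self):
        # most extreme of C(6,3)=20 assignments, doubled: p = 2/20
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.exact
        assert res.p_value == pytest.approx(0.1, abs=1e-12)

    def test_large_shift_four_vs_four_significant(self):
        res = wilcoxon_rank_sum([1.0, 1.2, 0.9, 1.1], [5.0, 5.2, 4.9, 5.1])
        assert res.p_value < 0.05

    @pytest.mark.parametrize("n_a,n_b,seed", [
        (2, 3, 0), (3, 3, 1), (4, 5, 2), (5, 5, 3), (6, 4, 4), (8, 8, 5),
        (3, 8, 6),
    ])
    def test_exact_p_equals_enumeration(self, n_a, n_b, seed):
        """DP-based exact null equals brute-force subset enumeration,
        including midrank ties."""
        rng = np.random.default_rng(seed)
        a = list(rng.integers(0, 6, n_a))      # integer draws force ties
        b = list(rng.integers(0, 6, n_b))
        if len(set(a) | set(b)) == 1:
            a[0] += 1
        res = wilcoxon_rank_sum(a, b)
        assert res.exact
        assert res.p_value == pytest.approx(enumerate_ranksum_p(a, b),
                                            abs=1e-12)

    @given(st.data())
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_exact_p_equals_enumeration_property(self, data):
        a = data.draw(st.lists(st.integers(0, 5), min_size=2, max_size=6))
        b = data.draw(st.lists(st.integers(0, 5), min_size=2, max_size=6))
        if len(set(a) | set(b)) == 1:
            return
        res = wilcoxon_rank_sum(a, b)
        assert res.p_value == pytest.approx(enumerate_ranksum_p(a, b),
                                            abs=1e-12)

    def test_large_sample_tracks_scipy_normal_approx(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 25)
        b = rng.normal(0.8, 1, 30)
        res = wilcoxon_rank_sum(a, b)
        assert not res.exact
        ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue, rel=0.02)


class TestKruskal:
    def test_identical_groups_h_zero(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_three_groups(self):
        groups = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]]
        res = kruskal_wallis(groups)
        # H = 12/(N(N+1)) * sum n_i (rbar_i - rbar)^2, no ties
        n = 9
        rbars = [2.0, 5.0, 8.0]
        h = 12.0 / (n * (n + 1)) * sum(3 * (r - 5.0) ** 2 for r in rbars)
        assert res.statistic == pytest.approx(h, rel=1e-12)

    def test_two_groups_redirects_to_rank_sum(self):
        with pytest.raises(ValueError, match="rank"):
            kruskal_wallis([[1, 2], [3, 4]])

    def test_gate_then_pairwise_at_adjusted_alpha(self):
        # n = 6 per group: the smallest exact two-sided rank-sum p (2/924)
        # clears the Bonferroni-adjusted alpha of 0.0167
        groups = {"young": [1.0, 1.1, 0.9, 1.2, 1.05, 0.95],
                  "adult": [1.0, 1.05, 0.95, 1.15, 0.9, 1.1],
                  "aged": [3.0, 3.1, 2.9, 3.2, 3.05, 2.95]}
        gate, pairwise, alpha = pairwise_after_kruskal(groups)
        assert alpha == 0.0167
        assert all(r.alpha_adjusted == pytest.approx(0.05 / 3)
                   for r in pairwise.values())
        sig = {k: r.significant for k, r in pairwise.items()}
        assert sig[("young", "aged")] or sig[("adult", "aged")]


class TestChiSquare:
    def test_expectation_table_statistic_zero(self):
        res = chi_square([[10, 20], [10, 20]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_diagonal_2x2_equals_twenty(self):
        res = chi_square([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0, rel=1e-12)

    def test_df_for_3x3(self):
        res = chi_square(np.ones((3, 3)) * 4)
        assert res.df == 4

    def test_zero_marginal_errors(self):
        with pytest.raises(ValueError):
            chi_square([[5, 0], [7, 0]])


class TestRegression:
    def test_perfect_line_r2_one(self):
        r2, slope = tonotopic_regression([0, 1, 2, 3], [10, 8, 6, 4])
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(-2.0)

    def test_flat_values_r2_zero(self):
        r2, _ = tonotopic_regression([0, 1, 2, 3], [5, 5, 5, 5])
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_constant_positions_error(self):
        with pytest.raises(ValueError):
            tonotopic_regression([2, 2, 2], [1, 2, 3])


class TestSummary:
    def test_mean_sem_cv(self):
        s = SummaryStat.from_sample([2.0, 4.0, 6.0])
        assert s.mean == pytest.approx(4.0)
        assert s.sem == pytest.approx(2.0 / np.sqrt(3))
        assert s.cv == pytest.approx(2.0 / 4.0)

    def test_zero_mean_flags_cv_undefined(self):
        s = SummaryStat.from_sample([-1.0, 1.0])
        assert s.cv is None
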