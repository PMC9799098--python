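"""Group-comparison statistics matching the study's testing scheme.

Two-group comparisons use the Wilcoxon rank-sum (Mann-Whitney) test with
midrank ties: the exact permutation null (computed by dynamic programming
over rank subsets) whenever the smaller sample has at most 8 observations,
and the continuity-corrected, tie-corrected normal approximation otherwise.
Three or more groups gate through Kruskal-Wallis; pairwise follow-ups apply
the Bonferroni-adjusted alpha (0.05 / m, e.g. 0.0167 for the three pairwise
age contrasts).  Categorical tables use the plain chi-square statistic
(no Yates correction).  All p-values are two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

ALPHA_NOMINAL = 0.05


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    n_per_group: tuple
    alpha_nominal: float = ALPHA_NOMINAL
    m_comparisons: int = 1
    df: int | None = None
    exact: bool | None = None

    @property
    def alpha_adjusted(self) -> float:
        return self.alpha_nominal / self.m_comparisons

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha_adjusted


@dataclass
class SummaryStat:
    mean: float
    sem: float
    cv: float | None
    n: int

    @classmethod
    def from_sample(cls, x) -> "SummaryStat":
        x = np.asarray(x, dtype=float)
        n = x.size
        mean = float(x.mean())
        sd = float(x.std(ddof=1)) if n > 1 else float("nan")
        sem = sd / np.sqrt(n) if n > 1 else float("nan")
        cv = sd / mean if (n > 1 and mean != 0) else None  # undefined at mean 0
        return cls(mean=mean, sem=sem, cv=cv, n=n)


def bonferroni_alpha(alpha: float = ALPHA_NOMINAL, m: int = 1) -> float:
    """Bonferroni-adjusted alpha = alpha / m, reported to 4 decimals."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return round(alpha / m, 4)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

_EXACT_MIN_N = 8


def _exact_ranksum_p(ranks2: np.ndarray, n_a: int, w_obs2: int) -> float:
    """Two-sided exact p for the rank-sum with midranks.

    ``ranks2`` are the pooled midranks doubled (integers); the null
    enumerates all C(N, n_a) equally likely subsets by a subset-sum DP and
    the two-sided p doubles the smaller tail (capped at 1).
    """
    total = int(ranks2.sum())
    # dp[k][s] = number of subsets of size k with doubled-rank sum s
    dp = np.zeros((n_a + 1, total + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        for k in range(min(n_a, 1_000_000), 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    counts = dp[n_a]
    n_total = counts.sum()
    lo = counts[: w_obs2 + 1].sum() / n_total
    hi = counts[w_obs2:].sum() / n_total
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_rank_sum(a, b, m_comparisons: int = 1) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    The statistic is the midrank sum of the first sample.  Exact null when
    ``min(len(a), len(b)) <= 8``; otherwise the normal approximation with
    continuity correction and the standard tie-corrected variance.  Samples
    that are completely tied across both groups give p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    w = float(ranks[: a.size].sum())
    n_a, n_b = a.size, b.size
    n = n_a + n_b

    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across both samples; p = 1")
        return TestResult("wilcoxon_rank_sum", w, 1.0, (n_a, n_b),
                          m_comparisons=m_comparisons, exact=True)

    if min(n_a, n_b) <= _EXACT_MIN_N:
        ranks2 = np.round(ranks * 2).astype(int)
        p = _exact_ranksum_p(ranks2, n_a, int(round(w * 2)))
        return TestResult("wilcoxon_rank_sum", w, p, (n_a, n_b),
                          m_comparisons=m_comparisons, exact=True)

    mu = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    z = (w - mu - 0.5 * np.sign(w - mu)) / np.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return TestResult("wilcoxon_rank_sum", w, min(1.0, p), (n_a, n_b),
                      m_comparisons=m_comparisons, exact=False)


def kruskal_wallis(groups, m_comparisons: int = 1) -> TestResult:
    """Kruskal-Wallis H (tie-corrected, chi-square reference)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError(
            "Kruskal-Wallis needs >= 3 groups; use wilcoxon_rank_sum for two"
        )
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*groups)
    return TestResult("kruskal_wallis", float(h), float(p),
                      tuple(g.size for g in groups),
                      m_comparisons=m_comparisons, df=len(groups) - 1)


def chi_square(table, m_comparisons: int = 1) -> TestResult:
    """Pearson chi-square on an r x c count table (no Yates correction)."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("table must be 2D")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal total; drop the empty row/column")
    chi2, p, df, expected = sps.chi2_contingency(table, correction=False)
    if np.any(expected <= 0):
        raise ValueError("all expected counts must be positive")
    return TestResult("chi_square", float(chi2), float(p),
                      tuple(int(x) for x in table.sum(axis=1)),
                      m_comparisons=m_comparisons, df=int(df))


def tonotopic_regression(positions, values) -> tuple[float, float]:
    """OLS of a morphometric quantity on tonotopic position: (R^2, slope)."""
    x = np.asarray(positions, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 points")
    if np.all(x == x[0]):
        raise ValueError("zero variance in positions")
    if np.all(y == y[0]):
        return 0.0, 0.0
    res = sps.linregress(x, y)
    return float(res.rvalue**2), float(res.slope)


def pairwise_after_kruskal(groups: dict, alpha: float = ALPHA_NOMINAL):
    """The study's scheme: Kruskal-Wallis gate, then pairwise rank-sum tests
    at the Bonferroni-adjusted alpha over all pairwise contrasts."""
    names = list(groups)
    gate = kruskal_wallis([groups[k] for k in names])
    pairs = [(i, j) for i in range(len(names)) for j in range(i + 1, len(names))]
    m = len(pairs)
    results = {}
    for i, j in pairs:
        r = wilcoxon_rank_sum(groups[names[i]], groups[names[j]],
                              m_comparisons=m)
        results[(names[i], names[j])] = r
    return gate, results, bonferroni_alpha(alpha, m)
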