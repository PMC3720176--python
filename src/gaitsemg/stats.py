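"""Trajectory similarity and small-sample nonparametric comparisons.

Curve similarity is scored with Spearman's rank correlation and labelled on
a conventional clinical interpretation scale. Condition effects within a
group use a Friedman omnibus test followed by pairwise Wilcoxon signed-rank
tests with Bonferroni correction; group differences use the Mann-Whitney U
test. At the study's sample sizes (8-9 subjects) asymptotic p-values are
unreliable, so the paired and two-sample tests compute exact permutation
p-values by default: the Wilcoxon null distribution is built by
convolution over the (possibly tied, average) ranks, which stays exact in
the presence of ties where textbook tables do not apply.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

logger = logging.getLogger("gaitsemg")

ALPHA = 0.05

#: interpretation scale for |rho|: the published bands (poor < 0.20,
#: fair 0.21-0.40, moderate 0.41-0.60, good 0.61-0.80, very good to
#: excellent 0.81-1.00) leave gaps between bands; bins are made half-open
#: at the midpoints so every coefficient gets a label.
SCALE_EDGES = (0.205, 0.405, 0.605, 0.805)
SCALE_LABELS = ("poor", "fair", "moderate", "good", "very good to excellent")


class DegenerateDataError(ValueError):
    """The data admit no test (constant input, all-zero differences...)."""


@dataclass
class SimilarityResult:
    """Spearman rho with the clinical magnitude label and sign."""

    rho: float
    p_value: float
    n_points: int
    magnitude_label: str
    sign: str


@dataclass
class TestResult:
    """A nonparametric test outcome with raw and optionally adjusted p."""

    method: str
    statistic: float
    p_raw: float
    n: object
    exact: bool
    p_adjusted: float | None = None


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------


def interpret_correlation(rho: float) -> tuple[str, str]:
    """(magnitude label, sign) for a correlation coefficient.

    The label is a monotone step function of |rho|; the sign is reported
    separately because the scale itself only grades magnitude.
    """
    if not np.isfinite(rho) or abs(rho) > 1.0:
        raise ValueError(f"correlation must lie in [-1, 1], got {rho}")
    idx = int(np.searchsorted(SCALE_EDGES, abs(rho), side="left"))
    return SCALE_LABELS[idx], ("+" if rho >= 0 else "-")


def spearman_similarity(a: np.ndarray, b: np.ndarray) -> SimilarityResult:
    """Spearman rank correlation between two equal-length trajectories.

    Average ranks for ties; rho is the Pearson correlation of the ranks and
    the two-sided p comes from the t approximation (reported for context,
    not used for gating).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("inputs must have equal length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateDataError("correlation undefined for a constant input")
    res = sps.spearmanr(a, b)
    rho = float(res.statistic)
    label, sign = interpret_correlation(rho)
    return SimilarityResult(rho=rho, p_value=float(res.pvalue), n_points=a.size,
                            magnitude_label=label, sign=sign)


# ---------------------------------------------------------------------------
# distributional screen
# ---------------------------------------------------------------------------


def shapiro_wilk(values: np.ndarray) -> TestResult:
    """Shapiro-Wilk normality screen (3 <= n <= 50).

    Reported for context only: downstream comparisons are always
    nonparametric regardless of the outcome.
    """
    values = np.asarray(values, dtype=float)
    if not 3 <= values.size <= 50:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 50, got {values.size}")
    if np.ptp(values) == 0:
        raise DegenerateDataError("Shapiro-Wilk undefined for a constant sample")
    w, p = sps.shapiro(values)
    return TestResult(method="shapiro_wilk", statistic=float(w), p_raw=float(p),
                      n=int(values.size), exact=False)


# ---------------------------------------------------------------------------
# within-group condition comparisons
# ---------------------------------------------------------------------------


def friedman(block_matrix: np.ndarray) -> TestResult:
    """Friedman rank test over a complete subjects x conditions matrix.

    Rows are ranked with average ties; the tie-corrected chi-square
    statistic Q is referred to chi2 with k-1 degrees of freedom. A matrix
    whose rows are all fully tied yields Q = 0, p = 1.
    """
    x = np.asarray(block_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a complete matrix with >= 2 subjects and >= 2 conditions")
    if np.any(~np.isfinite(x)):
        raise ValueError("matrix contains missing cells")
    n, k = x.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, x)
    col_sums = ranks.sum(axis=0)
    ssbn = float(np.sum(col_sums**2))
    ties = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    correction = 1.0 - ties / (k * (k * k - 1) * n)
    if correction == 0.0:  # every row fully tied
        return TestResult(method="friedman", statistic=0.0, p_raw=1.0,
                          n=(n, k), exact=False)
    q = (12.0 / (n * k * (k + 1)) * ssbn - 3.0 * n * (k + 1)) / correction
    p = float(sps.chi2.sf(q, k - 1))
    return TestResult(method="friedman", statistic=float(q), p_raw=p,
                      n=(n, k), exact=False)


def _exact_signed_rank_p(ranks: np.ndarray, w_min: float) -> float:
    """Exact two-sided p for the signed-rank statistic by convolution.

    Builds the null distribution of the positive-rank sum S+ over all 2^n
    equiprobable sign assignments. Average ranks are half-integers, so
    doubling makes every rank an exact integer and the distribution is a
    polynomial convolution. The two-sided p is
    P(S+ <= w) + P(S+ >= T - w) with w the smaller rank sum and T the total,
    which equals 2 P(S+ <= w) when the distribution is symmetric.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: counts.size - r].copy()
    counts /= 2.0 ** len(r2)
    w2 = int(np.rint(2.0 * w_min))
    p = counts[: w2 + 1].sum() + counts[total - w2 :].sum()
    return float(min(1.0, p))


def wilcoxon_signed_rank(
    paired_a: np.ndarray, paired_b: np.ndarray, exact_max_n: int = 25
) -> TestResult:
    """Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (the classical convention); the statistic
    W is the smaller of the two signed-rank sums. For n <= ``exact_max_n``
    non-zero differences the two-sided p is exact over all 2^n sign
    assignments (valid under ties via average ranks); beyond that the
    normal approximation with tie correction is used.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if n <= exact_max_n:
        p = _exact_signed_rank_p(ranks, w)
        exact = True
    else:
        mu = n * (n + 1) / 4.0
        tie_term = 0.0
        _, counts = np.unique(np.abs(d), return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / 48.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        z = (w - mu) / sigma
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        exact = False
    return TestResult(method="wilcoxon_signed_rank", statistic=w, p_raw=p,
                      n=int(n), exact=exact)


# ---------------------------------------------------------------------------
# between-group comparison
# ---------------------------------------------------------------------------


def mann_whitney_u(
    group_a: np.ndarray, group_b: np.ndarray, exact_max_product: int = 400
) -> TestResult:
    """Mann-Whitney U test between two independent samples.

    Statistic is the smaller of the two U values. The p-value is exact (full
    enumeration of group assignments) whenever ``n_a * n_b`` does not exceed
    ``exact_max_product`` and the pooled sample has no ties; otherwise the
    normal approximation with tie and continuity corrections is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = (a.size * b.size <= exact_max_product) and not has_ties
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if use_exact else "asymptotic",
    )
    u1 = float(res.statistic)
    u = min(u1, a.size * b.size - u1)
    return TestResult(method="mann_whitney_u", statistic=u,
                      p_raw=float(res.pvalue), n=(int(a.size), int(b.size)),
                      exact=use_exact)


# ---------------------------------------------------------------------------
# multiplicity and the full condition-comparison chain
# ---------------------------------------------------------------------------


def bonferroni(p_values, m: int) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m < p.size:
        raise ValueError(f"m = {m} smaller than the number of p-values ({p.size})")
    return np.minimum(1.0, m * p)


def compare_conditions(
    per_subject_values: np.ndarray,
    alpha: float = ALPHA,
    condition_labels: tuple[str, ...] = ("DGO", "DGO_therapist", "treadmill"),
) -> tuple[TestResult, list[TestResult], list[tuple[str, str]], list[bool]]:
    """Friedman omnibus plus Bonferroni-corrected pairwise Wilcoxon tests.

    ``per_subject_values`` is a complete subjects x conditions matrix.
    Returns (omnibus, pairwise results, condition pairs, significance flags);
    flags compare the Bonferroni-adjusted p against ``alpha``. A pair with
    all-zero differences is reported with p = 1 rather than an error.
    """
    x = np.asarray(per_subject_values, dtype=float)
    if x.ndim != 2 or x.shape[1] != len(condition_labels):
        raise ValueError(
            f"expected a subjects x {len(condition_labels)} matrix, got {x.shape}"
        )
    omnibus = friedman(x)
    pairs = [(i, j) for i in range(x.shape[1]) for j in range(i + 1, x.shape[1])]
    results: list[TestResult] = []
    for i, j in pairs:
        try:
            results.append(wilcoxon_signed_rank(x[:, i], x[:, j]))
        except DegenerateDataError:
            results.append(TestResult(
                method="wilcoxon_signed_rank", statistic=float("nan"),
                p_raw=1.0, n=int(x.shape[0]), exact=True,
            ))
    adjusted = bonferroni([r.p_raw for r in results], m=len(pairs))
    for r, p_adj in zip(results, adjusted):
        r.p_adjusted = float(p_adj)
    flags = [bool(r.p_adjusted < alpha) for r in results]
    pair_labels = [(condition_labels[i], condition_labels[j]) for i, j in pairs]
    return omnibus, results, pair_labels, flags
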