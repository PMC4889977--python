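"""Shared statistical primitives.

Thin, uniformly-typed wrappers around the classical tests the pipeline uses
(Fisher/binomial exact, Wilcoxon rank-sum, Welch t, Shapiro-Wilk,
Brown-Forsythe, variance-ratio F, chi-squared) plus multiple-testing
corrections.  Every test returns a :class:`TestResult` so downstream tables
are homogeneous.

Two-sided exact p-values are defined as the total probability of outcomes no
more likely than the observed one ("probability mass <= observed"), which is
what scipy computes; this differs from doubling the smaller tail for skewed
nulls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

TWO_SIDED = "two-sided"
LESS = "less"
GREATER = "greater"


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: float | None = None
    exact: bool = False
    effect: float | None = None  # odds ratio or location difference, test-specific
    ci_low: float | None = None
    ci_high: float | None = None
    note: str = ""

    def __post_init__(self) -> None:
        # guard against numerical overshoot; p = 0 is kept only for exact zeros
        if np.isfinite(self.p_value):
            self.p_value = float(min(max(self.p_value, 0.0), 1.0))


def fisher_exact(table, sided: str = TWO_SIDED, effect: bool = True) -> TestResult:
    """Fisher's exact test on a 2x2 count table.

    Two-sided p sums hypergeometric tables with probability <= observed;
    the effect is the conditional-MLE odds ratio with a 95% CI.  Pass
    ``effect=False`` to skip the (iterative) odds-ratio computation when
    only the p-value is needed in bulk.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    res = sps.fisher_exact(table, alternative=sided)
    if not effect:
        return TestResult(statistic=float(res.statistic),
                          p_value=float(res.pvalue), exact=True)
    orr = sps.contingency.odds_ratio(table, kind="conditional")
    try:
        ci = orr.confidence_interval(0.95)
        ci_low, ci_high = float(ci.low), float(ci.high)
    except Exception:  # degenerate margins
        ci_low = ci_high = None
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      exact=True, effect=float(orr.statistic),
                      ci_low=ci_low, ci_high=ci_high)


def binomial_exact(k: int, n: int, p0: float = 0.5, sided: str = TWO_SIDED) -> TestResult:
    """Exact binomial test of k successes in n trials against rate p0."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    res = sps.binomtest(int(k), int(n), p0, alternative=sided)
    return TestResult(statistic=float(k), p_value=float(res.pvalue), exact=True,
                      effect=float(res.statistic))


def wilcoxon_rank_sum(x, y, sided: str = TWO_SIDED) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney U) test.

    Uses the exact null when m + n <= 30 and there are no ties; otherwise the
    normal approximation with midranks and tie-corrected variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        logger.warning("all values identical across both groups; p = 1")
        return TestResult(statistic=float(x.size * y.size / 2), p_value=1.0, exact=True)
    has_ties = len(np.unique(pooled)) < pooled.size
    use_exact = (x.size + y.size <= 30) and not has_ties
    if has_ties and x.size + y.size <= 30:
        logger.debug("ties present: falling back to normal approximation")
    res = sps.mannwhitneyu(x, y, alternative=sided,
                           method="exact" if use_exact else "asymptotic")
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      exact=use_exact, effect=float(np.median(x) - np.median(y)))


def welch_t(x, y) -> TestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("need at least 3 observations per group")
    res = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      df=float(res.df), effect=float(x.mean() - y.mean()))


def shapiro_wilk(x) -> TestResult:
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk limited to n <= 5000")
    res = sps.shapiro(x)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue))


def brown_forsythe(x, y) -> TestResult:
    """Brown-Forsythe variance-equality test: ANOVA on |deviations from medians|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("need at least 3 observations per group")
    dx = np.abs(x - np.median(x))
    dy = np.abs(y - np.median(y))
    if np.var(np.concatenate([dx, dy])) == 0:
        return TestResult(statistic=0.0, p_value=1.0, df=float(x.size + y.size - 2))
    stat, p = sps.levene(x, y, center="median")
    return TestResult(statistic=float(stat), p_value=float(p),
                      df=float(x.size + y.size - 2))


def f_var_test(x, y) -> TestResult:
    """Two-sided variance-ratio F test (R var.test convention: F = s_x^2/s_y^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("need at least 3 observations per group")
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    dfx, dfy = x.size - 1, y.size - 1
    if vy == 0 and vx == 0:
        return TestResult(statistic=1.0, p_value=1.0, df=float(dfx))
    if vy == 0:
        return TestResult(statistic=np.inf, p_value=0.0, df=float(dfx))
    f = vx / vy
    cdf = sps.f.cdf(f, dfx, dfy)
    p = 2 * min(cdf, 1 - cdf)
    return TestResult(statistic=float(f), p_value=float(min(p, 1.0)),
                      df=float(dfx), effect=float(f))


def chisq_2xk(table) -> TestResult:
    """Chi-squared independence test on a 2 x k table."""
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        logger.warning("degenerate margin in chi-squared table; p = 1 by convention")
        return TestResult(statistic=0.0, p_value=1.0, df=0.0)
    res = sps.chi2_contingency(table, correction=False)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      df=float(res.dof))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, in input order)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni(pvals, m: int | None = None) -> np.ndarray | float:
    """Bonferroni adjustment: min(1, m*p).  Scalar in, scalar out."""
    scalar = np.isscalar(pvals)
    p = np.atleast_1d(np.asarray(pvals, dtype=float))
    m = int(m) if m is not None else p.size
    adj = np.minimum(1.0, m * p)
    return float(adj[0]) if scalar else adj
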