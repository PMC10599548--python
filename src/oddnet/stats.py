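"""Inferential procedures used in the analyses.

Thin, contract-stable wrappers around scipy.stats: one-sided Wilcoxon
signed-rank (with the Z statistic of the normal approximation), Pearson
correlation with a one-sided Wald test on the regression slope, bootstrap
percentile confidence intervals for the median, and Brown-Forsythe /
independent-samples t comparisons between two groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "wilcoxon_signed_rank_one_sided",
    "pearson_wald_one_sided",
    "bootstrap_median_ci",
    "variance_and_mean_comparisons",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: int
    direction: str
    name: str

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value out of range")


def _wilcoxon_z(d: np.ndarray, alternative: str) -> float:
    """Z statistic of the signed-rank normal approximation with tie
    correction and a continuity correction toward the alternative."""
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    cc = 0.5 if alternative == "greater" else -0.5
    if var <= 0:
        return 0.0
    return float((w_plus - mu - cc) / np.sqrt(var))


def wilcoxon_signed_rank_one_sided(
    values: np.ndarray, null_center: float = 0.0, alternative: str = "greater"
) -> TestResult:
    """One-sided Wilcoxon signed-rank test against a hypothesized center.

    Exact zeros are dropped (standard convention). p-values use exact
    enumeration for n <= 15 and the normal approximation with continuity
    correction otherwise; the reported statistic is always the
    approximation's Z, signed so that positive Z favors "greater".
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    d = np.asarray(values, dtype=float) - null_center
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all values equal the null center; test undefined")
    method = "exact" if n <= 15 else "approx"
    res = sps.wilcoxon(d, alternative=alternative, method=method, correction=True)
    return TestResult(
        statistic=_wilcoxon_z(d, alternative),
        p_value=float(res.pvalue),
        n=n,
        direction=alternative,
        name="wilcoxon_signed_rank",
    )


def pearson_wald_one_sided(
    xs: np.ndarray, ys: np.ndarray, alternative: str = "less"
) -> TestResult:
    """Pearson correlation with a one-sided Wald test on the OLS slope.

    The statistic is the correlation coefficient rho; the p-value comes
    from the Wald z of the regression slope (slope / its standard error,
    referred to the standard normal). ``alternative='less'`` tests for a
    negative association, ``'greater'`` for a positive one.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    n = len(xs)
    if n < 3:
        raise ValueError("need at least 3 points")
    if xs.std() == 0 or ys.std() == 0:
        raise ValueError("zero variance input")
    rho = float(np.corrcoef(xs, ys)[0, 1])
    if 1.0 - rho**2 < 1e-15:
        z = np.inf * np.sign(rho)
    else:
        # Wald z of the slope equals rho * sqrt(n - 2) / sqrt(1 - rho^2)
        z = rho * np.sqrt(n - 2) / np.sqrt(1.0 - rho**2)
    p = sps.norm.sf(z) if alternative == "greater" else sps.norm.cdf(z)
    return TestResult(
        statistic=rho, p_value=float(p), n=n, direction=alternative, name="pearson_wald"
    )


def bootstrap_median_ci(
    values: np.ndarray, n_boot: int = 10000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the median."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    medians = np.median(values[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(medians, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def variance_and_mean_comparisons(
    group_a: np.ndarray, group_b: np.ndarray
) -> dict[str, TestResult]:
    """Brown-Forsythe equality-of-variances test and pooled-variance
    independent-samples t-test between two groups."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    f_stat, f_p = sps.levene(a, b, center="median")
    t_stat, t_p = sps.ttest_ind(a, b, equal_var=True)
    n = len(a) + len(b)
    return {
        "brown_forsythe": TestResult(
            statistic=float(f_stat), p_value=float(f_p), n=n,
            direction="two-sided", name="brown_forsythe",
        ),
        "t_test": TestResult(
            statistic=float(t_stat), p_value=float(t_p), n=n,
            direction="two-sided", name="independent_t",
        ),
    }
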