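"""Group-level statistics: two-sample tests, chi-square, covariate-adjusted
comparison, Bonferroni correction and partial correlation.

The t-test is Welch's (unequal variances); recomputing cognitive-score
p-values from printed "mean +/- SEM" summaries reproduces published values
under the Welch degrees of freedom. Covariate adjustment is realized as the
t-test on the group coefficient of a least-squares model
``y ~ 1 + group + covariates``. Partial correlation correlates the residuals
of both variables after removing the covariates (plus intercept), with the
p-value from the t transform on n - k - 2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "SummaryStat",
    "GroupComparisonResult",
    "welch_t_from_summary",
    "welch_t",
    "mann_whitney",
    "chi_square_counts",
    "adjusted_group_compare",
    "bonferroni",
    "partial_correlation",
]


@dataclass(frozen=True)
class SummaryStat:
    """Printed summary of one group: mean, standard error of the mean, n."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.sem <= 0:
            raise ValueError("sem must be positive")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass
class GroupComparisonResult:
    """One test's outcome."""

    metric: str
    statistic: float
    stat_name: str
    df: float
    p: float
    p_adjusted: float | None = None
    reject: bool | None = None
    covariates: tuple[str, ...] = ()


def summarize(values) -> SummaryStat:
    """Mean +/- SEM summary of a sample."""
    x = np.asarray(values, dtype=float)
    return SummaryStat(mean=float(x.mean()), sem=float(x.std(ddof=1) / np.sqrt(x.size)), n=x.size)


def welch_t_from_summary(a: SummaryStat, b: SummaryStat, metric: str = "") -> GroupComparisonResult:
    """Welch two-sample t-test recomputed from per-group mean +/- SEM.

    t = (m_a - m_b) / sqrt(sem_a^2 + sem_b^2), with Welch-Satterthwaite df
    treating sem^2 as the variance of each group mean.
    """
    va, vb = a.sem**2, b.sem**2
    t = (a.mean - b.mean) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return GroupComparisonResult(metric=metric, statistic=float(t), stat_name="t", df=float(df), p=float(p))


def welch_t(data_a, data_b, metric: str = "") -> GroupComparisonResult:
    """Welch two-sample t-test on raw data (identical to the summary form)."""
    a = np.asarray(data_a, dtype=float)
    b = np.asarray(data_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return GroupComparisonResult(metric=metric, statistic=0.0, stat_name="t", df=float(a.size + b.size - 2), p=1.0)
        raise ValueError("both groups have zero variance but different means; t undefined")
    return welch_t_from_summary(summarize(a), summarize(b), metric=metric)


def mann_whitney(data_a, data_b, metric: str = "") -> GroupComparisonResult:
    """Mann-Whitney U test: exact for small tie-free samples (n <= 8 per
    group), otherwise the tie-corrected normal approximation."""
    a = np.asarray(data_a, dtype=float)
    b = np.asarray(data_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs n >= 1")
    no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 8 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparisonResult(
        metric=metric, statistic=float(res.statistic), stat_name="U", df=float("nan"), p=float(res.pvalue)
    )


def chi_square_counts(table, correction: bool = False, metric: str = "") -> GroupComparisonResult:
    """Pearson chi-square on a 2x2 count table (no continuity correction by default)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    chi2, p, df, _ = sps.chi2_contingency(t, correction=correction)
    return GroupComparisonResult(metric=metric, statistic=float(chi2), stat_name="chi2", df=float(df), p=float(p))


def adjusted_group_compare(y, group, covariates: pd.DataFrame | None = None, metric: str = "") -> GroupComparisonResult:
    """Group comparison adjusted for covariates.

    Fits ``y ~ 1 + group + covariates`` by least squares and reports the
    t-test on the group coefficient. With no covariates this is equivalent to
    the pooled two-sample t-test.
    """
    y = np.asarray(y, dtype=float)
    glabels = pd.Series(group)
    levels = pd.unique(glabels)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(levels)}")
    counts = glabels.value_counts()
    if counts.min() < 2:
        raise ValueError("each group needs at least 2 members")
    indicator = (glabels == levels[1]).to_numpy(dtype=float)
    cols = [np.ones_like(y), indicator]
    names = ["const", "group"]
    if covariates is not None and covariates.shape[1] > 0:
        cov = covariates.copy()
        for c in cov.columns:
            if cov[c].dtype == object or str(cov[c].dtype) == "category":
                cov[c] = pd.factorize(cov[c])[0]
        keep = [c for c in cov.columns if cov[c].std() > 0]
        for c in keep:
            cols.append(cov[c].to_numpy(dtype=float))
            names.append(str(c))
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(y, design).fit()
    return GroupComparisonResult(
        metric=metric,
        statistic=float(fit.tvalues[1]),
        stat_name="t",
        df=float(fit.df_resid),
        p=float(fit.pvalues[1]),
        covariates=tuple(names[2:]),
    )


def bonferroni(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni correction over a family of m tests.

    Returns (adjusted p-values, reject flags); reject iff raw p <= alpha/m,
    adjusted p = min(1, m*p).
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    adjusted = np.minimum(1.0, m * p)
    reject = p <= alpha / m
    return adjusted, reject


def partial_correlation(x, y, covariates: pd.DataFrame | np.ndarray | None = None) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on the covariates (plus intercept); r is
    the Pearson correlation of the residuals and p comes from
    ``t = r * sqrt((n - k - 2) / (1 - r^2))`` on n - k - 2 df. With no
    covariates this reduces to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    n = x.size
    if covariates is None:
        z = np.empty((n, 0))
    else:
        z = np.asarray(covariates, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
    k = z.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    design = np.column_stack([np.ones(n), z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise ValueError("a residual has zero variance; partial correlation undefined")
    r = float(np.clip((rx * ry).sum() / denom, -1.0, 1.0))
    df = n - k - 2
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return r, p
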