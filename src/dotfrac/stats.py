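"""Group statistics on ROI summary tables.

Non-parametric two-sample comparison (Mann-Whitney U), scan-rescan
reproducibility (two-way random-effects absolute-agreement single-measure
ICC(2,1)), covariate-adjusted group contrasts (OLS with a total-cerebellar-
volume covariate), one-way ANOVA with Tukey HSD post-hoc, and Bonferroni
thresholding of the family of metric/region comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

__all__ = [
    "StatResult",
    "mann_whitney",
    "icc",
    "anova_tukey",
    "adjusted_group_regression",
    "bonferroni_threshold",
]


@dataclass(frozen=True)
class StatResult:
    """One hypothesis test: statistic, raw p, and Bonferroni assessment."""

    test: str
    statistic: float
    p_value: float
    alpha_adj: float
    groups: tuple
    n: tuple
    effect: float = np.nan  # signed effect size where meaningful (e.g. OLS coef)

    def __post_init__(self):
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha_adj


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Adjusted per-comparison threshold alpha/m for m comparisons.

    With alpha = 0.05 over 15 comparisons (three metrics across five
    region-level analyses) the operative threshold is 0.05/15 = 0.0033.
    """
    if m < 1:
        raise ValueError("number of comparisons m must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    return alpha / m


def mann_whitney(x, y, alpha_adj: float = 0.05) -> StatResult:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when the combined sample size is <= 20
    and the data are tie-free; otherwise the normal approximation with tie
    correction (and continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return StatResult("mann-whitney", float(res.statistic), float(min(res.pvalue, 1.0)),
                      alpha_adj, ("x", "y"), (x.size, y.size))


def icc(measurements) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``measurements`` is a complete (subjects x sessions) matrix. Computed
    from the two-way ANOVA mean squares::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with n subjects, k sessions, MSR/MSC/MSE the row, column and residual
    mean squares. Absolute agreement: a constant shift between sessions
    lowers the coefficient.
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a (subjects >= 2) x (sessions >= 2) matrix")
    if not np.all(np.isfinite(m)):
        raise ValueError("missing cells are not supported (no imputation)")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0 if msr == mse else 0.0
    return float((msr - mse) / denom)


def anova_tukey(groups, labels=None, alpha_adj: float = 0.05) -> list[StatResult]:
    """One-way ANOVA omnibus plus Tukey HSD pairwise comparisons.

    ``groups`` is a list of samples (each n >= 2). Returns the omnibus
    F-test followed by one :class:`StatResult` per pair, with Tukey-
    adjusted p-values from the studentized-range distribution.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    f_res = sps.f_oneway(*groups)
    results = [StatResult("anova", float(f_res.statistic), float(f_res.pvalue),
                          alpha_adj, tuple(labels), tuple(g.size for g in groups))]
    hsd = sps.tukey_hsd(*groups)
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            results.append(StatResult(
                "tukey", float(hsd.statistic[i, j]), float(hsd.pvalue[i, j]),
                alpha_adj, (labels[i], labels[j]), (groups[i].size, groups[j].size),
                effect=float(np.mean(groups[i]) - np.mean(groups[j])),
            ))
    return results


def adjusted_group_regression(outcome, group, covariate, reference=None,
                              alpha_adj: float = 0.05) -> list[StatResult]:
    """OLS of outcome on group indicators plus a numeric covariate.

    One result per non-reference group: the coefficient is the adjusted
    group difference versus the reference (first group alphabetically
    unless given), its t-statistic and p-value from the OLS fit.
    """
    outcome = np.asarray(outcome, dtype=float)
    group = np.asarray(group)
    covariate = np.asarray(covariate, dtype=float)
    if not (outcome.size == group.size == covariate.size):
        raise ValueError("outcome, group and covariate must have equal length")
    levels = sorted(set(group.tolist()))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    if np.ptp(covariate) == 0:
        raise ValueError("covariate is constant (collinear with the intercept)")
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ValueError(f"reference group {reference!r} not present")
    others = [g for g in levels if g != reference]
    X = np.column_stack(
        [(group == g).astype(float) for g in others] + [covariate]
    )
    X = sm.add_constant(X)
    fit = sm.OLS(outcome, X).fit()
    results = []
    for idx, g in enumerate(others, start=1):
        n_g = int((group == g).sum())
        n_ref = int((group == reference).sum())
        results.append(StatResult(
            "ols-contrast", float(fit.tvalues[idx]), float(fit.pvalues[idx]),
            alpha_adj, (str(g), str(reference)), (n_g, n_ref),
            effect=float(fit.params[idx]),
        ))
    return results
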