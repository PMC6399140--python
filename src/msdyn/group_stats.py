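"""Cohort comparison of microstate properties.

Two-sample pooled-variance Student t-tests per feature, Bonferroni-Holm
step-down correction within each feature family (the 12 off-diagonal
transitions; the 4 durations; the 4 occurrence rates), Cohen's d effect
sizes, and numeric normality diagnostics.

Sign convention: statistics are computed as group1 - group2, so with group 1
the control cohort a positive d means controls are larger.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import InvalidInputError, UndefinedResultError


@dataclass
class ComparisonResult:
    """One feature's cohort comparison."""

    feature: str
    t_statistic: float
    df: int
    p_raw: float
    p_adjusted: float
    cohens_d: float
    significant: bool


def _check_samples(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InvalidInputError("each sample needs >= 2 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidInputError("samples contain non-finite values")
    return x, y


def _pooled_sd(x: np.ndarray, y: np.ndarray) -> float:
    n1, n2 = x.size, y.size
    return float(np.sqrt(((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1))
                         / (n1 + n2 - 2)))


def student_t_test(x, y) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test (x - y), two-sided.

    Returns (t, df, p) with df = n1 + n2 - 2.
    """
    x, y = _check_samples(x, y)
    df = x.size + y.size - 2
    if _pooled_sd(x, y) == 0:
        if x.mean() == y.mean():
            return 0.0, df, 1.0
        raise UndefinedResultError("zero variance with unequal means")
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), df, float(res.pvalue)


def holm_adjust(p_values) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values, in the input order.

    The i-th smallest raw p is multiplied by (m - i + 1), a running maximum
    enforces monotonicity, and values are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InvalidInputError("need a 1-D, nonempty p-value list")
    if np.any(p < 0) or np.any(p > 1):
        raise InvalidInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def cohens_d(x, y) -> float:
    """Cohen's d = (mean(x) - mean(y)) / pooled SD (n-1 weighted)."""
    x, y = _check_samples(x, y)
    sd = _pooled_sd(x, y)
    if sd == 0:
        raise UndefinedResultError("effect size undefined at zero pooled SD")
    return float((x.mean() - y.mean()) / sd)


def compare_cohorts(table1: pd.DataFrame, table2: pd.DataFrame,
                    family: list[str] | None = None, alpha: float = 0.05
                    ) -> list[ComparisonResult]:
    """Per-feature t-test + Cohen's d with Holm correction across the family.

    ``table1``/``table2`` are subjects x features frames sharing columns;
    ``family`` selects the columns corrected together (default: all shared
    columns as one family).  Significance is declared at adjusted p < alpha.
    """
    if family is None:
        family = list(table1.columns)
    missing = [f for f in family if f not in table1.columns
               or f not in table2.columns]
    if missing:
        raise InvalidInputError(f"features missing from a table: {missing}")
    raws: list[tuple[str, float, int, float, float]] = []
    for feat in family:
        t, df, p = student_t_test(table1[feat].to_numpy(),
                                  table2[feat].to_numpy())
        d = (0.0 if t == 0.0 and p == 1.0
             else cohens_d(table1[feat].to_numpy(), table2[feat].to_numpy()))
        raws.append((feat, t, df, p, d))
    adjusted = holm_adjust([r[3] for r in raws])
    return [ComparisonResult(feat, t, df, p, float(p_adj), d, p_adj < alpha)
            for (feat, t, df, p, d), p_adj in zip(raws, adjusted)]


def results_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    """Comparison results as a tidy table."""
    return pd.DataFrame(
        [{"feature": r.feature, "t": r.t_statistic, "df": r.df,
          "p_raw": r.p_raw, "p_holm": r.p_adjusted, "d": r.cohens_d,
          "significant": r.significant} for r in results])


def normality_diagnostics(x) -> tuple[float, float, float]:
    """Numeric stand-in for a visual Q-Q check:
    (skewness, excess kurtosis, Shapiro-Wilk p)."""
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise InvalidInputError("need n >= 8 for normality diagnostics")
    if x.var(ddof=1) == 0:
        raise UndefinedResultError("diagnostics undefined for a constant sample")
    skew = float(stats.skew(x))
    kurt = float(stats.kurtosis(x))  # excess (Fisher)
    shapiro_p = float(stats.shapiro(x[:5000] if x.size > 5000 else x).pvalue)
    return skew, kurt, shapiro_p
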