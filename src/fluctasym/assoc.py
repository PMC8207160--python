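"""Association battery relating FA indices to habitat and genetic factors.

Population-level comparisons use one-way ANOVA (normal data) or
Kruskal-Wallis (non-parametric); continuous relationships use Pearson
correlation; the relevance of each factor is assessed by a likelihood-ratio
test of a bivariate linear model against an intercept-only null; family-wise
error is controlled by Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "pearson_assoc",
    "group_tests",
    "lrt_vs_null",
    "bonferroni",
    "association_battery",
    "GroupTestResult",
]


def pearson_assoc(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need at least 3 paired values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class GroupTestResult:
    anova_f: float
    anova_p: float
    kruskal_h: float
    kruskal_p: float
    normal: bool          # Shapiro-Wilk gate on residuals at alpha = .05
    preferred: str        # "anova" if normal else "kruskal"
    dropped_groups: list


def group_tests(values, group_labels, normality_alpha: float = 0.05) -> GroupTestResult:
    """One-way ANOVA and Kruskal-Wallis across groups.

    Groups with fewer than 2 members are excluded with a warning.  Both test
    results are always reported; ``preferred`` follows a Shapiro-Wilk
    normality check of the within-group residuals.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups, dropped = [], []
    for lab in pd.unique(labels):
        g = values[labels == lab]
        if len(g) < 2:
            dropped.append(lab)
            warnings.warn(f"group {lab!r} has fewer than 2 members; excluded", stacklevel=2)
        else:
            groups.append(g)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with >= 2 members")

    if all(np.ptp(g) == 0 for g in groups) and np.ptp(np.concatenate(groups)) == 0:
        # all values identical: no variation at all
        return GroupTestResult(0.0, 1.0, 0.0, 1.0, True, "anova", dropped)

    f_stat, f_p = stats.f_oneway(*groups)
    try:
        h_stat, h_p = stats.kruskal(*groups)
    except ValueError:  # all values identical within the rank test
        h_stat, h_p = 0.0, 1.0
    residuals = np.concatenate([g - g.mean() for g in groups])
    if len(residuals) >= 3 and np.ptp(residuals) > 0:
        _, shapiro_p = stats.shapiro(residuals)
        normal = bool(shapiro_p >= normality_alpha)
    else:
        normal = True
    return GroupTestResult(
        anova_f=float(f_stat), anova_p=float(f_p),
        kruskal_h=float(h_stat), kruskal_p=float(h_p),
        normal=normal, preferred="anova" if normal else "kruskal",
        dropped_groups=dropped,
    )


def lrt_vs_null(y, x) -> tuple[float, float]:
    """Likelihood-ratio test of a bivariate normal linear model against the
    intercept-only null.

    chi2 = n * ln(RSS0 / RSS1), distributed chi2(1) under the null
    (equivalently chi2 = -n * ln(1 - r^2)).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1 or len(y) < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    n = len(y)
    rss0 = float(((y - y.mean()) ** 2).sum())
    X = np.column_stack([np.ones(n), x])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss1 = float(((y - X @ beta) ** 2).sum())
    if rss0 == 0.0:
        return 0.0, 1.0
    if rss1 <= 0.0:
        return float("inf"), 0.0
    chi2 = n * float(np.log(rss0 / rss1))
    chi2 = max(chi2, 0.0)
    return chi2, float(stats.chi2.sf(chi2, 1))


def bonferroni(alpha_family: float, m_tests: int) -> float:
    """Per-test alpha under Bonferroni control of the family-wise error."""
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return alpha_family / m_tests


def _encode(x: pd.Series) -> np.ndarray:
    """Numeric encoding for predictors; categorical factors become 0/1..g-1
    codes (the battery is bivariate, so two-level factors are exact)."""
    if pd.api.types.is_numeric_dtype(x):
        return x.to_numpy(dtype=float)
    codes, _ = pd.factorize(x, sort=True)
    return codes.astype(float)


def association_battery(
    data: pd.DataFrame,
    responses: list[str],
    factors: list[str],
    level: str,
    alpha_family: float = 0.05,
    m_tests: int | None = None,
) -> pd.DataFrame:
    """Likelihood-ratio tests of each factor against the null, per response.

    ``m_tests`` defaults to the number of factors; passing the configured
    family size reproduces a stricter per-test alpha when some factors are
    not available in the data.
    """
    m = m_tests if m_tests is not None else len(factors)
    alpha = bonferroni(alpha_family, m)
    rows = []
    for response in responses:
        for factor in factors:
            sub = data[[response, factor]].dropna()
            y = sub[response].to_numpy(dtype=float)
            x = _encode(sub[factor])
            try:
                chi2, p = lrt_vs_null(y, x)
            except ValueError:
                chi2, p = np.nan, np.nan
            rows.append(
                {
                    "level": level,
                    "response": response,
                    "factor": factor,
                    "n": len(sub),
                    "chi2": chi2,
                    "p": p,
                    "alpha_used": alpha,
                    "significant": bool(p < alpha) if np.isfinite(p) else False,
                }
            )
    return pd.DataFrame(rows)
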