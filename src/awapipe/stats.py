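"""Shared statistical kernel.

Every hypothesis test used across the pipeline lives here so that each test
family has a single implementation: two-sample t-test (Welch by default),
Bonferroni adjustment, Fisher exact and chi-squared tests on 2x2 tables, and
two-way fixed-effects ANOVA. Downstream modules re-export these rather than
calling scipy/statsmodels directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    ``p_adj`` is the Bonferroni-adjusted p-value, ``min(1, p_raw * n_comparisons)``.
    """

    statistic: float
    p_raw: float
    p_adj: float
    n_comparisons: int
    method: str


def _adjust(p: float, m: int) -> float:
    return float(min(1.0, p * m))


def two_sample_t(
    a, b, equal_var: bool = False, n_comparisons: int = 1
) -> TestResult:
    """Two-tailed two-sample t-test (Welch unless ``equal_var``).

    Degenerate case: two identical constant samples have no evidence of a
    difference, so the result is t = 0, p = 1 rather than NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    method = "student-t" if equal_var else "welch-t"
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return TestResult(0.0, 1.0, _adjust(1.0, n_comparisons),
                              n_comparisons, method)
        raise ValueError("both samples constant with unequal means: "
                         "t-test undefined (zero variance)")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return TestResult(float(t), float(p), _adjust(float(p), n_comparisons),
                      n_comparisons, method)


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni adjustment: each p becomes min(1, p * m), m = family size."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


def _check_2x2(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    return t


def _zero_margin(t: np.ndarray) -> bool:
    return bool(np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0))


def fisher_exact_2x2(table, alternative: str = "greater") -> tuple[float, float]:
    """Fisher exact test on a 2x2 table; returns (odds ratio, p).

    A table with a zero margin carries no information about association;
    p = 1 is returned with a warning.
    """
    t = _check_2x2(table)
    if _zero_margin(t):
        warnings.warn("2x2 table has a zero margin; returning p = 1")
        return float("nan"), 1.0
    odds, p = sps.fisher_exact(t, alternative=alternative)
    return float(odds), float(p)


def chi_squared_2x2(
    table, yates: bool = False, fisher_fallback: bool = True
) -> TestResult:
    """Chi-squared test of independence on a 2x2 table.

    No Yates continuity correction by default. When any expected cell count
    is below 5 the asymptotic chi-squared approximation is unreliable; with
    ``fisher_fallback`` (default) a two-sided Fisher exact test is used
    instead and the result's ``method`` records the switch.
    """
    t = _check_2x2(table)
    if _zero_margin(t):
        warnings.warn("2x2 table has a zero margin; returning p = 1")
        return TestResult(float("nan"), 1.0, 1.0, 1, "degenerate")
    expected = sps.contingency.expected_freq(t)
    if fisher_fallback and expected.min() < 5:
        _, p = sps.fisher_exact(t, alternative="two-sided")
        return TestResult(float("nan"), float(p), float(p), 1, "fisher-exact")
    stat, p, _, _ = sps.chi2_contingency(t, correction=yates)
    return TestResult(float(stat), float(p), float(p), 1, "chi-squared")


def two_way_anova(
    data: pd.DataFrame, value: str, factor_a: str, factor_b: str
) -> dict[str, tuple[float, float]]:
    """Two-way fixed-effects ANOVA with interaction.

    Parameters
    ----------
    data
        Long-format table; one row per observation.
    value, factor_a, factor_b
        Column names of the response and the two categorical factors.

    Returns
    -------
    dict mapping ``factor_a``, ``factor_b`` and ``"interaction"`` to
    (F statistic, p-value).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = data.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    counts = df.groupby(["_a", "_b"], observed=True).size()
    full = df["_a"].nunique() * df["_b"].nunique()
    if len(counts) < full or (counts < 1).any():
        raise ValueError("empty cell in the two-way design")
    model = smf.ols("_y ~ C(_a) * C(_b)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    out = {}
    for key, row_name in [
        (factor_a, "C(_a)"),
        (factor_b, "C(_b)"),
        ("interaction", "C(_a):C(_b)"),
    ]:
        out[key] = (float(tab.loc[row_name, "F"]), float(tab.loc[row_name, "PR(>F)"]))
    return out
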