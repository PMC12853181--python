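"""Statistical test contracts used across the NOR analyses.

Thin, uniformly-shaped wrappers over scipy / statsmodels: paired and
one-sample t tests, Pearson correlation, Shapiro-Wilk normality, the exact
binomial test, Benjamini-Hochberg adjustment, and a fixed-effects three-way
ANOVA (facility x object material x side) with interactions.  Degenerate
inputs (zero variance, n < 2) are flagged rather than raised so cohort
pipelines can propagate them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "paired_t",
    "one_sample_t",
    "two_sample_t",
    "pearson",
    "bh_adjust",
    "exact_binomial",
    "shapiro_wilk",
    "three_way_anova",
]


@dataclass(frozen=True)
class StatResult:
    """Uniform test result: statistic, p-value, degrees of freedom, flag.

    ``flag`` is None for a clean result, otherwise a short reason the test
    was degenerate (its statistic/p are then NaN).
    """

    statistic: float
    pvalue: float
    df: float | None = None
    flag: str | None = None

    @property
    def ok(self) -> bool:
        return self.flag is None


def _degenerate(reason: str, df: float | None = None) -> StatResult:
    return StatResult(float("nan"), float("nan"), df=df, flag=reason)


def paired_t(a, b) -> StatResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples differ in length")
    if a.size < 2:
        return _degenerate("n < 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        return _degenerate("zero variance of differences", df=a.size - 1)
    res = sps.ttest_rel(a, b)
    return StatResult(float(res.statistic), float(res.pvalue), df=a.size - 1)


def one_sample_t(x, popmean: float) -> StatResult:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return _degenerate("n < 2")
    if np.allclose(x.std(ddof=1), 0.0):
        return _degenerate("zero variance", df=x.size - 1)
    res = sps.ttest_1samp(x, popmean)
    return StatResult(float(res.statistic), float(res.pvalue), df=x.size - 1)


def two_sample_t(a, b) -> StatResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        return _degenerate("n < 2 in a group")
    res = sps.ttest_ind(a, b)
    return StatResult(float(res.statistic), float(res.pvalue), df=a.size + b.size - 2)


def pearson(x, y) -> StatResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y differ in length")
    if x.size < 3:
        return _degenerate("n < 3")
    if np.allclose(x.std(), 0.0) or np.allclose(y.std(), 0.0):
        return _degenerate("zero variance")
    res = sps.pearsonr(x, y)
    return StatResult(float(res.statistic), float(res.pvalue), df=x.size - 2)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def exact_binomial(k: int, n: int, p: float = 0.5, alternative: str = "greater") -> StatResult:
    """Exact binomial test, one-sided toward the novel-first direction by
    default (``alternative='greater'``); two-sided available by flag."""
    if n < 1:
        return _degenerate("n < 1")
    res = sps.binomtest(k, n, p, alternative=alternative)
    return StatResult(k / n, float(res.pvalue))


def shapiro_wilk(x) -> StatResult:
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return _degenerate("n < 3")
    res = sps.shapiro(x)
    return StatResult(float(res.statistic), float(res.pvalue))


def three_way_anova(
    data: pd.DataFrame,
    response: str = "exploration_s",
    factors: tuple[str, str, str] = ("facility", "object", "side"),
) -> pd.DataFrame:
    """Fixed-effects three-way ANOVA with all interactions.

    Type II sums of squares (robust to mild imbalance; in balanced designs
    the SS types coincide).  Returns the statsmodels ANOVA table with rows
    for each main effect, each interaction, and the residual.
    """
    for col in (response, *factors):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    a, b, c = factors
    formula = f"{response} ~ C({a}) * C({b}) * C({c})"
    model = ols(formula, data=data).fit()
    return anova_lm(model, typ=2)
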