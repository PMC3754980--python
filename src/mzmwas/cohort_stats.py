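"""Case/control cohort balance statistics.

Categorical covariates (smoking, comorbidities, supplement use) are
compared with the two-tailed Fisher exact test; continuous covariates
(age) with a two-tailed t-test, computable from raw values or from
published mean/SD/n summaries alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import lgamma
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CASE, CONTROL, ValidationError

# Relative tolerance for point-probability ties in the two-sided Fisher sum;
# the dominant software convention.
_FISHER_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b, c, d) = cases with / cases without / controls with /
    controls without the attribute."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValidationError("2x2 counts must be non-negative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValidationError("2x2 table is empty")


@dataclass(frozen=True)
class GroupSummary:
    """Published summary of a continuous variable in one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")
        if self.n < 2:
            raise ValidationError("n must be >= 2")


def _log_hypergeom_pmf(k: int, n1: int, n2: int, c1: int) -> float:
    """log P(K = k) for K ~ Hypergeometric(row1=n1, row2=n2, col1=c1)."""

    def lchoose(n: int, r: int) -> float:
        return lgamma(n + 1) - lgamma(r + 1) - lgamma(n - r + 1)

    return lchoose(n1, k) + lchoose(n2, c1 - k) - lchoose(n1 + n2, c1)


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p by point-probability summation.

    Sums the hypergeometric probabilities of all tables with the observed
    margins whose point probability does not exceed the observed one
    (relative tie tolerance 1e-7).  Log-gamma arithmetic keeps the sum
    stable for large counts.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n1, n2, c1 = a + b, c + d, a + c
    if n1 == 0 or n2 == 0 or c1 == 0 or b + d == 0:
        warnings.warn("degenerate 2x2 margin; Fisher p = 1", stacklevel=2)
        return 1.0
    lo = max(0, c1 - n2)
    hi = min(n1, c1)
    support = np.arange(lo, hi + 1)
    logpmf = np.array([_log_hypergeom_pmf(int(k), n1, n2, c1) for k in support])
    pmf = np.exp(logpmf)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1 + _FISHER_TIE_RTOL)].sum())
    return min(p, 1.0)


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    pvalue: float
    variant: str


def _welch_df(v1: float, n1: int, v2: float, n2: int) -> float:
    num = (v1 / n1 + v2 / n2) ** 2
    den = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    return num / den if den > 0 else float(n1 + n2 - 2)


def t_test_two_sided(
    x: Union[Sequence[float], GroupSummary],
    y: Union[Sequence[float], GroupSummary],
    variant: str = "welch",
) -> TTestResult:
    """Two-tailed two-sample t-test (Welch by default, pooled optional).

    Accepts raw value vectors or :class:`GroupSummary` objects, so printed
    cohort summaries can be re-tested without the underlying data.
    """
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    equal_var = variant == "pooled"
    if isinstance(x, GroupSummary) or isinstance(y, GroupSummary):
        if not (isinstance(x, GroupSummary) and isinstance(y, GroupSummary)):
            raise ValueError("mix of raw values and summaries is not supported")
        m1, s1, n1 = x.mean, x.sd, x.n
        m2, s2, n2 = y.mean, y.sd, y.n
    else:
        xa = np.asarray(x, float)
        ya = np.asarray(y, float)
        xa = xa[~np.isnan(xa)]
        ya = ya[~np.isnan(ya)]
        if len(xa) < 2 or len(ya) < 2:
            raise ValidationError("each group needs >= 2 values")
        m1, s1, n1 = xa.mean(), xa.std(ddof=1), len(xa)
        m2, s2, n2 = ya.mean(), ya.std(ddof=1), len(ya)
    v1, v2 = s1**2, s2**2
    if v1 == 0 and v2 == 0:
        t = 0.0 if m1 == m2 else float(np.sign(m1 - m2)) * np.inf
        df = float(n1 + n2 - 2)
        return TTestResult(t, df, 1.0 if m1 == m2 else 0.0, variant)
    res = stats.ttest_ind_from_stats(
        m1, s1, n1, m2, s2, n2, equal_var=equal_var
    )
    df = float(n1 + n2 - 2) if equal_var else _welch_df(v1, n1, v2, n2)
    return TTestResult(float(res.statistic), df, float(res.pvalue), variant)


def cohort_balance_table(
    samples: pd.DataFrame, variant: str = "welch"
) -> pd.DataFrame:
    """One row per covariate: case stat, control stat, and a two-tailed p.

    Numeric covariates with more than two distinct values get a t-test and
    are summarised as ``mean+/-sd``; binary/boolean covariates get a Fisher
    exact test and are summarised as ``with/total``.  Covariates missing
    for every sample are skipped with a warning.
    """
    rows = []
    case = samples[samples["group"] == CASE]
    ctrl = samples[samples["group"] == CONTROL]
    for col in samples.columns:
        if col == "group":
            continue
        series = samples[col]
        if series.isna().all():
            warnings.warn(f"covariate {col!r} missing for all samples; skipped")
            continue
        xc, yc = case[col].dropna(), ctrl[col].dropna()
        is_binary = series.dropna().nunique() <= 2
        if pd.api.types.is_numeric_dtype(series) and not is_binary:
            res = t_test_two_sided(xc.to_numpy(float), yc.to_numpy(float), variant)
            rows.append(
                {
                    "variable": col,
                    "test": f"t ({variant})",
                    "case_stat": f"{xc.mean():.1f}+/-{xc.std(ddof=1):.1f}",
                    "control_stat": f"{yc.mean():.1f}+/-{yc.std(ddof=1):.1f}",
                    "p": res.pvalue,
                }
            )
        else:
            levels = sorted(series.dropna().unique(), key=str)
            positive = levels[-1]  # True / 1 / lexicographically last level
            a = int((xc == positive).sum())
            b = int(len(xc) - a)
            c = int((yc == positive).sum())
            d = int(len(yc) - c)
            p = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
            rows.append(
                {
                    "variable": col,
                    "test": "fisher",
                    "case_stat": f"{a}/{a + b}",
                    "control_stat": f"{c}/{c + d}",
                    "p": p,
                }
            )
    return pd.DataFrame(rows, columns=["variable", "test", "case_stat", "control_stat", "p"])
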