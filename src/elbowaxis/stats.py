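"""Cohort-level statistics: summaries, normality, t-tests, and ICC.

The normality check and Student's t-tests are delegated to scipy.stats.  The
intraclass correlation coefficients are computed here from the two-way ANOVA
mean squares in the McGraw & Wong formulation:

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    ICC(3,1) = (MSR - MSE) / (MSR + (k-1) MSE)

with MSR/MSC/MSE the rows (targets), columns (raters) and error mean squares
of an n x k single-measurement layout.  ICC(2,1) is the two-way random,
absolute-agreement coefficient; ICC(3,1) the two-way mixed, consistency one.
Significance (H0: ICC = 0) uses F = MSR/MSE with (n-1, (n-1)(k-1)) df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError

__all__ = ["summarize", "shapiro_wilk", "t_test", "icc", "rater_table_from_long",
           "TTestResult", "ICCResult"]


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise mean and sample SD (n-1 denominator) of a cohort table."""
    numeric = table.select_dtypes("number")
    if len(numeric) < 2:
        raise ValueError("cohort summary needs at least 2 specimens")
    return pd.DataFrame({"mean": numeric.mean(), "sd": numeric.std(ddof=1)})


def shapiro_wilk(sample) -> tuple[float, float]:
    """Shapiro-Wilk W and p for 3 <= n <= 5000 samples."""
    x = np.asarray(sample, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got n={x.size}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("Shapiro-Wilk is undefined for a constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    paired: bool
    degenerate: bool = False


def t_test(x, y, paired: bool = True) -> TTestResult:
    """Two-sided Student's t-test; paired by default (same specimens).

    A paired test with zero-variance differences (including x == y) is
    returned flagged degenerate with t=0, p=1 rather than raising.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if paired:
        if x.size != y.size:
            raise ValueError("paired t-test needs equal-length samples")
        d = x - y
        if np.ptp(d) == 0:
            return TTestResult(t=0.0, df=float(x.size - 1), p=1.0, paired=True,
                               degenerate=True)
        res = sps.ttest_rel(x, y)
        return TTestResult(float(res.statistic), float(res.df), float(res.pvalue), True)
    res = sps.ttest_ind(x, y, equal_var=True)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue), False)


@dataclass(frozen=True)
class ICCResult:
    model: str   # 'ICC2' or 'ICC3'
    value: float
    F: float
    df1: int
    df2: int
    p: float


def _two_way_mean_squares(data: np.ndarray):
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((data - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc(ratings, model: str = "ICC2") -> ICCResult:
    """Single-rater ICC from a complete targets x raters table.

    ``ratings`` is an (n_targets, k_raters) array or DataFrame of single
    measurements (wide layout).  ``model`` selects ICC(2,1) (two-way random,
    absolute agreement) or ICC(3,1) (two-way mixed, consistency).
    """
    if model not in ("ICC2", "ICC3"):
        raise ValueError("model must be 'ICC2' or 'ICC3'")
    data = np.asarray(ratings, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("ICC needs a complete 2-way layout with >= 2 targets and raters")
    if np.isnan(data).any():
        raise ValueError("ICC layout is incomplete (NaN entries)")
    n, k = data.shape
    msr, msc, mse = _two_way_mean_squares(data)
    if model == "ICC2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    else:
        denom = msr + (k - 1) * mse
    value = 0.0 if denom == 0 else (msr - mse) / denom
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if mse == 0:
        F = np.inf if msr > 0 else np.nan
        p = 0.0 if msr > 0 else np.nan
    else:
        F = msr / mse
        p = float(sps.f.sf(F, df1, df2))
    return ICCResult(model=model, value=float(value), F=float(F), df1=df1, df2=df2, p=p)


def rater_table_from_long(df: pd.DataFrame, parameter: str,
                          sessions: str = "mean") -> pd.DataFrame:
    """Wide targets x raters table for one parameter from a long rater file.

    Expects columns (specimen, rater, session, parameter, value).  Sessions
    are averaged per (specimen, rater) by default, matching an inter-observer
    design; pass ``sessions='first'`` to keep only the first session.
    """
    needed = {"specimen", "rater", "session", "parameter", "value"}
    if not needed <= set(df.columns):
        raise ValueError(f"rater table needs columns {sorted(needed)}")
    sub = df[df.parameter == parameter]
    if sub.empty:
        raise ValueError(f"no ratings for parameter {parameter!r}")
    if sessions == "first":
        first = sub.session.min()
        sub = sub[sub.session == first]
        wide = sub.pivot(index="specimen", columns="rater", values="value")
    else:
        wide = sub.pivot_table(index="specimen", columns="rater", values="value",
                               aggfunc="mean")
    if wide.isna().any().any():
        raise ValueError(f"incomplete rater layout for parameter {parameter!r}")
    return wide
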