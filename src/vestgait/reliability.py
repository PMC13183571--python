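"""Test-retest reliability via single-measure intraclass correlation.

The two analyzed walks per condition are treated as the repeated
measures (columns) of a two-way subjects x walks layout.  Both
single-measure ICC conventions of the two-way model are implemented:

* ``consistency`` — ICC(3,1) of Shrout & Fleiss / ICC(C,1) of McGraw &
  Wong: ``(MSR - MSE) / (MSR + (k-1) MSE)``; systematic walk-to-walk
  offsets do not count as disagreement.
* ``absolute_agreement`` — ICC(A,1) under the two-way mixed model:
  ``(MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))``.

Confidence intervals use the exact F interval for the consistency form
and the McGraw-Wong interval with Satterthwaite degrees of freedom for
absolute agreement.  The F test of subject discriminability is
``MSR/MSE`` on ``(n-1, (n-1)(k-1))`` degrees of freedom in both forms.

Interpretation bands follow the common guideline cut-points: below 0.5
poor, 0.5-0.75 moderate, 0.75-0.9 good, above 0.9 excellent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

FORMS = ("consistency", "absolute_agreement")

#: Interpretation cut-points (half-open; values exactly at 0.5 and 0.75
#: fall in the higher band, 0.9 still counts as good).
BAND_EDGES = (0.5, 0.75, 0.9)


@dataclass
class ReliabilityResult:
    """ICC point estimate with its ANOVA backbone and interpretation."""

    metric: str
    condition: str
    n: int
    k: int
    form: str
    icc: float
    ci_low: float
    ci_high: float
    f_stat: float
    p: float
    band: str
    ms_rows: float
    ms_cols: float
    ms_error: float


class MissingCellError(ValueError):
    """The subjects x walks matrix still has missing cells after listwise drop."""


def anova_mean_squares(matrix: np.ndarray) -> tuple[float, float, float, int, int]:
    """Two-way mean squares of an n x k repeated-measures matrix.

    Rows are subjects, columns are walks.  Subjects with any missing
    value are dropped listwise.  Returns ``(ms_rows, ms_cols, ms_error,
    n, k)`` where ``n`` is the number of complete subjects retained.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D subjects x walks matrix")
    complete = ~np.isnan(m).any(axis=1)
    m = m[complete]
    n, k = m.shape
    if n < 3 or k < 2:
        raise MissingCellError(
            f"need >= 3 complete subjects and >= 2 walks, got n={n}, k={k}"
        )
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((m - grand) ** 2).sum())
    ss_error = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_error = ss_error / ((n - 1) * (k - 1))
    return ms_rows, ms_cols, ms_error, n, k


def icc_from_mean_squares(
    ms_rows: float,
    ms_cols: float,
    ms_error: float,
    n: int,
    k: int,
    form: str = "absolute_agreement",
    metric: str = "",
    condition: str = "",
) -> ReliabilityResult:
    """Single-measure ICC point estimate with F test from ANOVA mean squares."""
    if form not in FORMS:
        raise ValueError(f"form must be one of {FORMS}, got '{form}'")
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if ms_error == 0.0:
        # zero residual: F test degenerates, p below any representable tail
        f_stat = math.inf
        p = 0.0
    else:
        f_stat = ms_rows / ms_error
        p = float(stats.f.sf(f_stat, df1, df2))
    if form == "consistency":
        denom = ms_rows + (k - 1) * ms_error
    else:
        denom = ms_rows + (k - 1) * ms_error + (k / n) * (ms_cols - ms_error)
    icc = 1.0 if denom == 0.0 else (ms_rows - ms_error) / denom
    result = ReliabilityResult(
        metric=metric,
        condition=condition,
        n=n,
        k=k,
        form=form,
        icc=float(icc),
        ci_low=math.nan,
        ci_high=math.nan,
        f_stat=float(f_stat),
        p=p,
        band=classify_band(icc),
        ms_rows=ms_rows,
        ms_cols=ms_cols,
        ms_error=ms_error,
    )
    result.ci_low, result.ci_high = icc_confidence_interval(result)
    return result


def icc_confidence_interval(
    result: ReliabilityResult, level: float = 0.95
) -> tuple[float, float]:
    """Confidence interval for the ICC of ``result``.

    Consistency form: exact interval from the F distribution of
    ``MSR/MSE``.  Absolute agreement: McGraw-Wong approximation with
    Satterthwaite degrees of freedom for the denominator.
    """
    n, k = result.n, result.k
    alpha = 1.0 - level
    if result.icc >= 1.0 or (result.form == "consistency" and result.ms_error == 0.0):
        return 1.0, 1.0
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if result.form == "consistency":
        fobs = result.ms_rows / result.ms_error
        fl = fobs / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = fobs * stats.f.ppf(1 - alpha / 2, df2, df1)
        low = (fl - 1) / (fl + k - 1)
        high = (fu - 1) / (fu + k - 1)
        return float(low), float(high)

    msr, msc, mse = result.ms_rows, result.ms_cols, result.ms_error
    icc = result.icc
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else math.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else math.inf
    if not math.isfinite(a):
        return 1.0, 1.0
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den
    f_low = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_up = stats.f.ppf(1 - alpha / 2, v, n - 1)
    low = (n * (msr - f_low * mse)) / (
        f_low * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    high = (n * (f_up * msr - mse)) / (
        k * msc + (k * n - k - n) * mse + n * f_up * msr
    )
    return float(low), float(high)


def classify_band(icc: float) -> str:
    """Interpretation band of an ICC value."""
    if not math.isfinite(icc):
        raise ValueError(f"ICC must be finite, got {icc}")
    if icc < BAND_EDGES[0]:
        return "poor"
    if icc < BAND_EDGES[1]:
        return "moderate"
    if icc <= BAND_EDGES[2]:
        return "good"
    return "excellent"


def estimate_reliability(
    matrix: np.ndarray,
    form: str = "absolute_agreement",
    metric: str = "",
    condition: str = "",
) -> ReliabilityResult:
    """ICC of a subjects x walks matrix (ANOVA + point estimate + CI)."""
    ms_rows, ms_cols, ms_error, n, k = anova_mean_squares(matrix)
    return icc_from_mean_squares(
        ms_rows, ms_cols, ms_error, n, k, form=form, metric=metric, condition=condition
    )


def icc_oracle(matrix: np.ndarray, form: str) -> float:
    """Brute-force ICC via an explicit least-squares two-way fit.

    Fits the additive subjects + walks model by dummy-coded ``lstsq``,
    obtains the sums of squares from sequential model fits, converts
    them to variance-component estimates and assembles the ICC from
    those.  Shares no code with :func:`icc_from_mean_squares`; used as
    an independent cross-check in the test-suite.
    """
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    y = m.ravel()
    subj = np.repeat(np.arange(n), k)
    walk = np.tile(np.arange(k), n)

    def rss(design: np.ndarray) -> float:
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        return float(resid @ resid)

    ones = np.ones((n * k, 1))
    d_subj = np.eye(n)[subj]
    d_walk = np.eye(k)[walk]
    rss_null = rss(ones)
    rss_subj = rss(np.hstack([ones, d_subj]))
    rss_full = rss(np.hstack([ones, d_subj, d_walk]))
    ss_rows = rss_null - rss_subj
    ss_cols = rss_subj - rss_full
    ss_err = rss_full
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    var_subj = (msr - mse) / k
    var_walk = (msc - mse) / n
    if form == "consistency":
        denom = var_subj + mse
    elif form == "absolute_agreement":
        denom = var_subj + var_walk + mse
    else:
        raise ValueError(f"unknown form '{form}'")
    if denom == 0:
        return 1.0
    return float(var_subj / denom)


def reliability_table(
    pairs_by_cell: dict[tuple[str, str], pd.DataFrame],
    form: str = "absolute_agreement",
) -> pd.DataFrame:
    """Reliability report: one row per condition x metric.

    ``pairs_by_cell`` maps (condition, metric) to a subjects x walks
    DataFrame (outlier-filtered).  Mean and SD pool the values of both
    walks, matching the single mean +/- SD reported per condition.
    """
    rows = []
    for (condition, metric), pairs in pairs_by_cell.items():
        values = pairs.to_numpy(dtype=float)
        res = estimate_reliability(values, form=form, metric=metric, condition=condition)
        pooled = values[~np.isnan(values).any(axis=1)].ravel()
        rows.append(
            {
                "condition": condition,
                "metric": metric,
                "n": res.n,
                "mean": float(np.mean(pooled)),
                "sd": float(np.std(pooled, ddof=1)),
                "icc": res.icc,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "f_stat": res.f_stat,
                "p": res.p,
                "band": res.band,
                "form": res.form,
            }
        )
    return pd.DataFrame(rows)
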