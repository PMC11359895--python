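"""Reliability and validity metrics: ICC(2,k), MAPE, group contrasts.

The test-retest ICC is the two-way random-effects, absolute-agreement,
average-of-k-measurements form computed from the mean squares of the
two-way ANOVA decomposition, with an F-distribution 95% confidence interval
(McGraw & Wong convention: the single-rater bounds are transformed to the
average-measures scale by the Spearman-Brown step).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError

__all__ = ["IccResult", "icc_2k", "mape", "stratified_contrast"]


@dataclass
class IccResult:
    icc: float
    ci95: tuple[float, float]
    n_subjects: int
    k_days: int
    ms_rows: float
    ms_cols: float
    ms_error: float

    def __post_init__(self) -> None:
        if self.icc > 1 + 1e-12:
            raise ValueError("ICC cannot exceed 1")


def icc_2k(matrix: np.ndarray, alpha: float = 0.05) -> IccResult:
    """ICC(2,k) of a subjects x days matrix (rows with missing cells dropped).

    Mean squares of the two-way layout with n rows and k columns:
      MSR = k * var of row means        (between-subjects)
      MSC = n * var of column means     (between-days)
      MSE = residual mean square
    ICC(2,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise EstimationError("matrix must be 2-D (subjects x days)")
    complete = np.all(np.isfinite(m), axis=1)
    m = m[complete]
    n, k = m.shape
    if n < 2 or k < 2:
        raise EstimationError(
            f"need >= 2 complete subjects and >= 2 days, got {n} x {k}"
        )
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

    denom = msr + (msc - mse) / n
    icc_k = 1.0 if denom == 0 else (msr - mse) / denom

    # single-rater ICC(2,1) and its F-based CI (McGraw & Wong), then
    # Spearman-Brown to the average-measures scale
    denom1 = msr + (k - 1) * mse + k * (msc - mse) / n
    icc_1 = 0.0 if denom1 == 0 else (msr - mse) / denom1
    if mse == 0 and msc == mse:
        lo_k, hi_k = icc_k, icc_k
    else:
        a = (k * icc_1) / (n * (1 - icc_1)) if icc_1 < 1 else np.inf
        b = 1 + (k * icc_1 * (n - 1)) / (n * (1 - icc_1)) if icc_1 < 1 else np.inf
        if np.isfinite(a):
            num_v = (a * msc + b * mse) ** 2
            den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            v = num_v / den_v if den_v > 0 else (n - 1) * (k - 1)
            f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo_1 = n * (msr - f1 * mse) / (
                f1 * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            hi_1 = n * (f2 * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f2 * msr
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                lo_k = k * lo_1 / (1 + (k - 1) * lo_1)
                hi_k = k * hi_1 / (1 + (k - 1) * hi_1)
        else:
            lo_k, hi_k = icc_k, icc_k
    lo_k = min(lo_k, icc_k)
    hi_k = min(max(hi_k, icc_k), 1.0)
    return IccResult(
        icc=float(icc_k),
        ci95=(float(lo_k), float(hi_k)),
        n_subjects=n,
        k_days=k,
        ms_rows=float(msr),
        ms_cols=float(msc),
        ms_error=float(mse),
    )


def mape(predicted: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """Mean and SD of the absolute percentage error |pred - truth| / |truth|.

    Raises on a zero truth entry, naming its index.
    """
    pred = np.asarray(predicted, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if pred.shape != tru.shape:
        raise ValueError("predicted and truth differ in length")
    if pred.size == 0:
        raise ValueError("empty input")
    zeros = np.flatnonzero(tru == 0)
    if zeros.size:
        raise ValueError(f"truth is zero at index {int(zeros[0])}")
    ape = np.abs(pred - tru) / np.abs(tru) * 100.0
    return float(ape.mean()), float(ape.std())


def stratified_contrast(
    values: np.ndarray,
    groups: np.ndarray,
    parametric: bool = True,
) -> pd.DataFrame:
    """Descriptive group summaries plus a delegated omnibus p-value.

    Parametric: mean/SD with t-test (2 groups) or one-way ANOVA; otherwise
    median/IQR with Mann-Whitney U or Kruskal-Wallis.  The p-value is
    recorded verbatim from the standard routine in ``DataFrame.attrs``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = [g for g in pd.unique(groups)]
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in names]
    rows = []
    for g, s in zip(names, samples):
        row = {"group": g, "n": int(s.size)}
        if s.size:
            if parametric:
                row["mean"] = float(s.mean())
                row["sd"] = float(s.std(ddof=1)) if s.size > 1 else np.nan
            else:
                row["median"] = float(np.median(s))
                row["iqr"] = float(np.percentile(s, 75) - np.percentile(s, 25))
        rows.append(row)
    df = pd.DataFrame(rows)
    nonempty = [s for s in samples if s.size > 1]
    if len(nonempty) >= 2:
        if parametric:
            if len(nonempty) == 2:
                stat, p = stats.ttest_ind(*nonempty)
                test = "t-test"
            else:
                stat, p = stats.f_oneway(*nonempty)
                test = "one-way ANOVA"
        else:
            if len(nonempty) == 2:
                stat, p = stats.mannwhitneyu(*nonempty)
                test = "Mann-Whitney U"
            else:
                stat, p = stats.kruskal(*nonempty)
                test = "Kruskal-Wallis"
        df.attrs.update({"test": test, "statistic": float(stat), "p_value": float(p)})
    return df
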