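"""Shared low-level signal helpers: quantiles and autocorrelation peaks.

The quantile rule (linear interpolation between order statistics) is defined
once here and used everywhere a percentile appears, so daily variability,
walking-speed percentiles and normative tables are mutually consistent.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks

__all__ = ["quantile", "unbiased_autocorr", "autocorr_step_peaks"]

#: search range for the step-period autocorrelation peak, seconds
STEP_LAG_RANGE_S = (0.25, 1.0)
#: minimum normalized autocorrelation coefficient for a credible step peak
MIN_STEP_PEAK = 0.25
#: stride peak searched at double the step lag within this relative window
STRIDE_LAG_TOL = 0.25
#: the step peak is the FIRST peak whose coefficient reaches this fraction
#: of the strongest peak in range (the stride-period peak at double the lag
#: can be higher than the step peak; taking the global maximum would halve
#: the detected cadence)
FIRST_PEAK_DOMINANCE = 0.5


def quantile(values: np.ndarray, q: float) -> float:
    """Percentile (q in [0, 100]) by linear interpolation of order statistics."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("quantile of empty array")
    return float(np.percentile(arr, q, method="linear"))


def unbiased_autocorr(x: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Unbiased autocorrelation of a 1-D signal, normalized to 1 at lag 0.

    r[k] = (1/(N-k)) * sum_i x[i] x[i+k], divided by r[0].  The mean is
    removed first so a constant offset does not masquerade as periodicity.
    Values are clipped to [-1, 1] (the unbiased estimator can slightly
    exceed the bound at large lags).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if max_lag is None:
        max_lag = n - 1
    max_lag = min(max_lag, n - 1)
    xc = x - x.mean()
    # FFT-based raw autocovariance
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(xc, nfft)
    raw = np.fft.irfft(spec * np.conj(spec), nfft)[: max_lag + 1]
    counts = n - np.arange(max_lag + 1)
    r = raw / counts
    if r[0] <= 0:
        return np.zeros(max_lag + 1)
    out = r / r[0]
    return np.clip(out, -1.0, 1.0)


def autocorr_step_peaks(
    ac: np.ndarray, fs: float
) -> tuple[float, float, float, float] | None:
    """Locate the step- and stride-period peaks of an autocorrelation.

    Returns ``(step_lag_s, step_coef, stride_lag_s, stride_coef)`` where the
    stride entries are NaN when no second peak exists, or None when no
    credible step peak is found (aperiodic signal).

    The step peak is the first dominant local maximum with lag in
    ``STEP_LAG_RANGE_S``: the smallest lag whose coefficient reaches both
    ``MIN_STEP_PEAK`` and ``FIRST_PEAK_DOMINANCE`` x the strongest peak in
    range.  The stride peak is the highest local maximum within +/-25% of
    double the step lag.
    """
    lo = int(round(STEP_LAG_RANGE_S[0] * fs))
    hi = int(round(STEP_LAG_RANGE_S[1] * fs))
    hi = min(hi, ac.size - 1)
    if hi <= lo + 1:
        return None
    peaks, _ = find_peaks(ac[: hi + 1])
    peaks = peaks[(peaks >= lo) & (peaks <= hi)]
    if peaks.size == 0:
        return None
    best = float(np.max(ac[peaks]))
    if best < MIN_STEP_PEAK:
        return None
    dominant = peaks[
        (ac[peaks] >= MIN_STEP_PEAK) & (ac[peaks] >= FIRST_PEAK_DOMINANCE * best)
    ]
    step_lag = int(dominant[0])
    step_coef = float(ac[step_lag])

    target = 2 * step_lag
    s_lo = int(np.floor(target * (1 - STRIDE_LAG_TOL)))
    s_hi = int(np.ceil(target * (1 + STRIDE_LAG_TOL)))
    s_hi = min(s_hi, ac.size - 1)
    stride_lag_s = float("nan")
    stride_coef = float("nan")
    if s_hi > s_lo + 1:
        speaks, _ = find_peaks(ac[: s_hi + 1])
        speaks = speaks[(speaks >= s_lo) & (speaks <= s_hi)]
        if speaks.size > 0:
            sl = int(speaks[np.argmax(ac[speaks])])
            stride_lag_s = sl / fs
            stride_coef = float(ac[sl])
    return step_lag / fs, step_coef, stride_lag_s, stride_coef
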