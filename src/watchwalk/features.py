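"""Per-window 54-dimensional feature vectors for the two SVM stages.

The feature set (version ``ww-54-v1``) spans time-domain statistics,
frequency-domain band powers and spectral shape of the band-passed norm,
autocorrelation peak value/lag at the step and stride periods, per-axis raw
summaries, inter-axis correlations of the band-passed axes, jerk statistics
and gravity-subtracted (ENMO-style) magnitude summaries.  The order is fixed
and versioned: a trained model only applies to matrices carrying the same
feature version.
"""

from __future__ import annotations

import numpy as np

from ._signal import unbiased_autocorr, autocorr_step_peaks
from .config import PipelineConfig
from .errors import DataError
from .preprocess import WindowFrame

__all__ = [
    "FEATURE_VERSION",
    "FEATURE_NAMES",
    "extract_features",
    "static_removed_magnitude",
]

FEATURE_VERSION = "ww-54-v1"

FEATURE_NAMES: tuple[str, ...] = (
    # band-passed norm, time domain
    "bp_mean", "bp_sd", "bp_median", "bp_iqr", "bp_min", "bp_max", "bp_rms",
    "bp_skew", "bp_kurtosis", "bp_sma", "bp_zero_crossings", "bp_mad",
    "bp_p5", "bp_p25", "bp_p75", "bp_p95",
    # band-passed norm, frequency domain
    "dom_freq_hz", "dom_freq_power_frac", "spectral_entropy", "spectral_centroid_hz",
    "bandpower_025_075", "bandpower_075_125", "bandpower_125_175", "bandpower_175_250",
    # autocorrelation peaks
    "ac_step_peak", "ac_step_lag_s", "ac_stride_peak", "ac_stride_lag_s",
    # raw axes
    "ax_mean", "ay_mean", "az_mean",
    "ax_sd", "ay_sd", "az_sd",
    "ax_range", "ay_range", "az_range",
    # band-passed axes
    "bpx_sd", "bpy_sd", "bpz_sd",
    "corr_xy", "corr_xz", "corr_yz",
    # jerk of the band-passed norm
    "jerk_mean", "jerk_sd",
    # crude (raw) norm
    "crude_mean", "crude_sd", "crude_median", "crude_iqr", "crude_min", "crude_max",
    # gravity-subtracted magnitude (ENMO-style)
    "enmo_mean", "enmo_median", "enmo_iqr",
)

assert len(FEATURE_NAMES) == 54


def static_removed_magnitude(raw_norm: np.ndarray) -> np.ndarray:
    """Gravity-subtracted magnitude: max(|a| - 1 g, 0) per sample (ENMO)."""
    arr = np.asarray(raw_norm, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DataError("non-finite values in raw norm stream")
    return np.maximum(arr - 1.0, 0.0)


def _moments(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise mean, sd, skewness, excess kurtosis; 0 where sd == 0."""
    mean = x.mean(axis=1)
    d = x - mean[:, None]
    m2 = (d**2).mean(axis=1)
    sd = np.sqrt(m2)
    ok = sd > 0
    skew = np.zeros_like(mean)
    kurt = np.zeros_like(mean)
    m3 = (d**3).mean(axis=1)
    m4 = (d**4).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        skew[ok] = m3[ok] / m2[ok] ** 1.5
        kurt[ok] = m4[ok] / m2[ok] ** 2 - 3.0
    return mean, sd, skew, kurt


def _row_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation; 0 where either row is constant."""
    da = a - a.mean(axis=1, keepdims=True)
    db = b - b.mean(axis=1, keepdims=True)
    num = (da * db).sum(axis=1)
    den = np.sqrt((da**2).sum(axis=1) * (db**2).sum(axis=1))
    out = np.zeros(a.shape[0])
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return np.clip(out, -1.0, 1.0)


def extract_features(frame: WindowFrame, cfg: PipelineConfig) -> np.ndarray:
    """Feature matrix of shape (n_windows, 54) in ``FEATURE_NAMES`` order.

    Deterministic; dispersion-type features are exactly 0 on constant input.
    """
    w_expect = int(round(cfg.window_s * cfg.sampling_rate_hz))
    if frame.n_windows and frame.samples_per_window != w_expect:
        raise DataError(
            f"windows carry {frame.samples_per_window} samples, expected {w_expect}"
        )
    n = frame.n_windows
    out = np.zeros((n, 54))
    if n == 0:
        return out
    fs = frame.sampling_rate_hz
    F = frame.filtered_norm
    R = frame.raw_norm
    A = frame.raw_axes
    FA = frame.filtered_axes
    if not (np.all(np.isfinite(F)) and np.all(np.isfinite(A))):
        raise DataError("non-finite samples in window data")

    col = {name: i for i, name in enumerate(FEATURE_NAMES)}

    mean, sd, skew, kurt = _moments(F)
    out[:, col["bp_mean"]] = mean
    out[:, col["bp_sd"]] = sd
    out[:, col["bp_median"]] = np.median(F, axis=1)
    p5, p25, p75, p95 = np.percentile(F, [5, 25, 75, 95], axis=1, method="linear")
    out[:, col["bp_iqr"]] = p75 - p25
    out[:, col["bp_min"]] = F.min(axis=1)
    out[:, col["bp_max"]] = F.max(axis=1)
    out[:, col["bp_rms"]] = np.sqrt((F**2).mean(axis=1))
    out[:, col["bp_skew"]] = skew
    out[:, col["bp_kurtosis"]] = kurt
    out[:, col["bp_sma"]] = np.abs(F).mean(axis=1)
    signs = np.signbit(F)
    out[:, col["bp_zero_crossings"]] = (signs[:, 1:] != signs[:, :-1]).sum(axis=1)
    out[:, col["bp_mad"]] = np.median(np.abs(F - np.median(F, axis=1)[:, None]), axis=1)
    out[:, col["bp_p5"]] = p5
    out[:, col["bp_p25"]] = p25
    out[:, col["bp_p75"]] = p75
    out[:, col["bp_p95"]] = p95

    # spectrum of the band-passed norm (mean removed; rfft, one-sided power)
    Fc = F - mean[:, None]
    spec = np.fft.rfft(Fc, axis=1)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(F.shape[1], d=1.0 / fs)
    power[:, 0] = 0.0
    total = power.sum(axis=1)
    ok = total > 0
    dom_idx = power.argmax(axis=1)
    out[ok, col["dom_freq_hz"]] = freqs[dom_idx[ok]]
    out[ok, col["dom_freq_power_frac"]] = power[ok, dom_idx[ok]] / total[ok]
    with np.errstate(divide="ignore", invalid="ignore"):
        p_norm = power[ok] / total[ok, None]
        plogp = np.where(p_norm > 0, p_norm * np.log(p_norm), 0.0)
        n_bins = power.shape[1] - 1  # DC excluded
        out[ok, col["spectral_entropy"]] = -plogp.sum(axis=1) / np.log(n_bins)
        out[ok, col["spectral_centroid_hz"]] = (power[ok] * freqs).sum(axis=1) / total[ok]
    for name, lo, hi in (
        ("bandpower_025_075", 0.25, 0.75),
        ("bandpower_075_125", 0.75, 1.25),
        ("bandpower_125_175", 1.25, 1.75),
        ("bandpower_175_250", 1.75, 2.50),
    ):
        band = (freqs >= lo) & (freqs < hi)
        out[ok, col[name]] = power[ok][:, band].sum(axis=1) / total[ok]

    # autocorrelation step/stride peaks (loop: peak search is per-window)
    max_lag = min(F.shape[1] - 1, int(round(2.5 * fs)))
    for i in range(n):
        if sd[i] == 0:
            continue
        ac = unbiased_autocorr(F[i], max_lag)
        found = autocorr_step_peaks(ac, fs)
        if found is None:
            continue
        step_lag, step_coef, stride_lag, stride_coef = found
        out[i, col["ac_step_peak"]] = step_coef
        out[i, col["ac_step_lag_s"]] = step_lag
        if np.isfinite(stride_coef):
            out[i, col["ac_stride_peak"]] = stride_coef
            out[i, col["ac_stride_lag_s"]] = stride_lag

    for j, axis in enumerate("xyz"):
        out[:, col[f"a{axis}_mean"]] = A[:, :, j].mean(axis=1)
        out[:, col[f"a{axis}_sd"]] = A[:, :, j].std(axis=1)
        out[:, col[f"a{axis}_range"]] = A[:, :, j].max(axis=1) - A[:, :, j].min(axis=1)
        out[:, col[f"bp{axis}_sd"]] = FA[:, :, j].std(axis=1)

    out[:, col["corr_xy"]] = _row_corr(FA[:, :, 0], FA[:, :, 1])
    out[:, col["corr_xz"]] = _row_corr(FA[:, :, 0], FA[:, :, 2])
    out[:, col["corr_yz"]] = _row_corr(FA[:, :, 1], FA[:, :, 2])

    jerk = np.diff(F, axis=1) * fs
    out[:, col["jerk_mean"]] = np.abs(jerk).mean(axis=1)
    out[:, col["jerk_sd"]] = jerk.std(axis=1)

    out[:, col["crude_mean"]] = R.mean(axis=1)
    out[:, col["crude_sd"]] = R.std(axis=1)
    rq25, rq50, rq75 = np.percentile(R, [25, 50, 75], axis=1, method="linear")
    out[:, col["crude_median"]] = rq50
    out[:, col["crude_iqr"]] = rq75 - rq25
    out[:, col["crude_min"]] = R.min(axis=1)
    out[:, col["crude_max"]] = R.max(axis=1)

    enmo = np.maximum(R - 1.0, 0.0)
    out[:, col["enmo_mean"]] = enmo.mean(axis=1)
    eq25, eq50, eq75 = np.percentile(enmo, [25, 50, 75], axis=1, method="linear")
    out[:, col["enmo_median"]] = eq50
    out[:, col["enmo_iqr"]] = eq75 - eq25

    if not np.all(np.isfinite(out)):
        raise DataError("non-finite feature values computed")
    return out
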