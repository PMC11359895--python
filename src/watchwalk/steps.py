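"""Step detection, cadence/variability episodes and gait regularity.

Steps are candidate peaks of the band-passed norm (minimum spacing 0.25 s,
prominence >= 0.25 x window RMS) cross-checked against the window's
autocorrelation: peaks are kept only when their median spacing agrees with
the autocorrelation step period within +/-20%, which rejects aperiodic
noise.  Detected steps are regrouped into 8-step episodes (7 intervals;
episode duration runs from first to last step) for cadence and step-time
variability; the daily variability is the 95th percentile of episode SDs.
Step and stride regularity are the normalized autocorrelation coefficients
at the step- and stride-period peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from ._signal import quantile, unbiased_autocorr, autocorr_step_peaks
from .bouts import WalkingBout
from .config import PipelineConfig
from .errors import WatchWalkError
from .labels import WALKING_STAGE1
from .preprocess import WindowFrame

__all__ = [
    "Episode",
    "StepSeries",
    "RegularityPair",
    "DailyStepMetrics",
    "detect_steps",
    "corrective_step_count",
    "episode_metrics",
    "regularity",
    "steps_in_bouts",
    "daily_regularity",
]

#: minimum spacing between step peaks, seconds (caps cadence at 4 steps/s)
MIN_PEAK_SPACING_S = 0.25
#: prominence threshold as a fraction of window RMS
PROMINENCE_RMS_FRACTION = 0.25
#: relative tolerance between median peak spacing and autocorrelation period
PERIOD_AGREEMENT_TOL = 0.20


@dataclass
class Episode:
    step_indices: list[int]
    duration_s: float
    cadence_spm: float
    step_time_sd_ms: float


@dataclass
class StepSeries:
    """Detected steps grouped by walking bout, plus the corrective count."""

    step_times_by_bout: list[np.ndarray]
    corrective_steps: float = 0.0

    @property
    def detected_steps(self) -> int:
        return int(sum(t.size for t in self.step_times_by_bout))

    @property
    def total_steps(self) -> float:
        return self.detected_steps + self.corrective_steps


@dataclass(frozen=True)
class RegularityPair:
    step_regularity: float
    stride_regularity: float

    def __post_init__(self) -> None:
        for v in (self.step_regularity, self.stride_regularity):
            if np.isfinite(v) and not (-1.0 <= v <= 1.0):
                raise ValueError(f"regularity outside [-1, 1]: {v}")


@dataclass
class DailyStepMetrics:
    cadence_median_spm: float | None
    cadence_iqr_spm: float | None
    step_time_variability_ms: float | None
    episodes: list[Episode] = field(default_factory=list)


def detect_steps(
    filtered_norm: np.ndarray, cfg: PipelineConfig
) -> np.ndarray:
    """Step event times (seconds from window start) within one walking window.

    Degenerate or aperiodic windows return an empty array, never an error.
    """
    x = np.asarray(filtered_norm, dtype=float)
    fs = cfg.sampling_rate_hz
    rms = float(np.sqrt(np.mean(x**2)))
    if rms <= 0:
        return np.zeros(0)
    ac = unbiased_autocorr(x, min(x.size - 1, int(round(2.5 * fs))))
    found = autocorr_step_peaks(ac, fs)
    if found is None:
        return np.zeros(0)
    period = found[0] * fs  # samples
    peaks, _ = find_peaks(
        x,
        distance=max(int(round(MIN_PEAK_SPACING_S * fs)), 1),
        prominence=PROMINENCE_RMS_FRACTION * rms,
    )
    if peaks.size < 2:
        return np.zeros(0)
    # snap a period-spaced comb to the detected peaks: harmonic sub-peaks
    # between steps are skipped and a momentarily weak step does not derail
    # the count.  Every detected peak is tried as the comb anchor; the comb
    # matching the most (then the strongest) peaks wins, so an anchor on a
    # spurious between-step hump cannot hijack the grid.
    tol = 0.3 * period

    def _snap(anchor: int) -> np.ndarray:
        k_lo = -int(np.floor(anchor / period)) - 1
        k_hi = int(np.floor((x.size - anchor) / period)) + 1
        hits = []
        for k in range(k_lo, k_hi + 1):
            target = anchor + k * period
            if target < -tol or target > x.size - 1 + tol:
                continue
            near = peaks[np.abs(peaks - target) <= tol]
            if near.size:
                hits.append(int(near[np.argmin(np.abs(near - target))]))
        return np.unique(hits)

    kept = np.zeros(0, dtype=int)
    best_score = (-1, -np.inf)
    for anchor in peaks:
        cand = _snap(int(anchor))
        score = (cand.size, float(x[cand].sum()) if cand.size else -np.inf)
        if score > best_score:
            best_score, kept = score, cand
    if kept.size < 2:
        return np.zeros(0)
    spacing = np.median(np.diff(kept))
    if abs(spacing - period) > PERIOD_AGREEMENT_TOL * period:
        return np.zeros(0)
    return kept / fs


def corrective_step_count(stage1: np.ndarray, model_rate: float) -> float:
    """Steps credited for unspecified-arms-walking windows.

    ``model_rate`` is the mean ground-truth steps per such window estimated
    during training and persisted in the classifier metadata.
    """
    if model_rate < 0:
        raise WatchWalkError(f"corrective rate must be non-negative: {model_rate}")
    n = int(np.sum(np.asarray(stage1, dtype=object) == "unspecified_arms_walking"))
    return model_rate * n


def steps_in_bouts(
    frame: WindowFrame,
    stage1: np.ndarray,
    bouts: list[WalkingBout],
    cfg: PipelineConfig,
    corrective_rate: float = 0.0,
) -> StepSeries:
    """Detect steps in every walking window of every bout.

    Detection stays per-window, but each window borrows up to 0.5 s of
    context from its contiguous neighbours so a peak landing on a window
    boundary is not lost; only peaks inside the window proper are kept, so
    no step is counted twice.  Step times are absolute (recording seconds).
    Bridged gaps contribute no steps; the corrective count covers
    unspecified-arms-walking windows.
    """
    fs = cfg.sampling_rate_hz
    w = frame.samples_per_window
    pad = int(round(0.5 * fs))
    by_bout = []
    for bout in bouts:
        times: list[np.ndarray] = []
        for run in _contiguous_runs(bout.window_indices, frame.start_times, cfg):
            sig = frame.filtered_norm[run].reshape(-1)
            base_t = frame.start_times[run[0]]
            for j in range(len(run)):
                o = j * w
                lo = max(0, o - pad)
                seg = sig[lo : min(sig.size, o + w + pad)]
                rel = detect_steps(seg, cfg)
                if rel.size == 0:
                    continue
                abs_idx = np.round(rel * fs).astype(int) + lo
                keep = (abs_idx >= o) & (abs_idx < o + w)
                if keep.any():
                    times.append(base_t + abs_idx[keep] / fs)
        by_bout.append(np.sort(np.concatenate(times)) if times else np.zeros(0))
    corrective = corrective_step_count(stage1, corrective_rate)
    return StepSeries(step_times_by_bout=by_bout, corrective_steps=corrective)


def _contiguous_runs(
    indices: list[int], start_times: np.ndarray, cfg: PipelineConfig
) -> list[list[int]]:
    """Split a bout's window indices at bridged gaps / recording breaks."""
    runs: list[list[int]] = [[indices[0]]]
    for prev, cur in zip(indices, indices[1:]):
        contiguous = (cur == prev + 1) and (
            abs(start_times[cur] - start_times[prev] - cfg.window_s) < 1e-6
        )
        if contiguous:
            runs[-1].append(cur)
        else:
            runs.append([cur])
    return runs


def episode_metrics(series: StepSeries, cfg: PipelineConfig) -> DailyStepMetrics:
    """Cadence median/IQR and step-time variability from 8-step episodes.

    Episodes never span bout boundaries; the trailing partial episode of a
    bout is discarded.  With no complete episode, all metrics are missing.
    """
    k = cfg.episode_steps
    episodes: list[Episode] = []
    for times in series.step_times_by_bout:
        if times.size < 2:
            continue
        # break the sequence where a step was evidently missed (interval far
        # above the bout's median): episodes must span consecutive steps
        intervals_all = np.diff(times)
        med = float(np.median(intervals_all))
        cut = np.flatnonzero(intervals_all > 1.8 * med) + 1
        for run in np.split(times, cut):
            for s in range(0, run.size - k + 1, k):
                chunk = run[s : s + k]
                _append_episode(episodes, chunk, s, k)
    if not episodes:
        return DailyStepMetrics(None, None, None, [])
    cad = np.asarray([e.cadence_spm for e in episodes])
    sds = np.asarray([e.step_time_sd_ms for e in episodes])
    return DailyStepMetrics(
        cadence_median_spm=quantile(cad, 50),
        cadence_iqr_spm=quantile(cad, 75) - quantile(cad, 25),
        step_time_variability_ms=quantile(sds, cfg.variability_percentile),
        episodes=episodes,
    )


def _append_episode(episodes: list[Episode], chunk: np.ndarray, s: int, k: int) -> None:
    duration = float(chunk[-1] - chunk[0])
    if duration > 0:
        intervals = np.diff(chunk)
        episodes.append(
            Episode(
                step_indices=list(range(s, s + k)),
                duration_s=duration,
                cadence_spm=60.0 * (k - 1) / duration,
                step_time_sd_ms=float(np.std(intervals) * 1000.0),
            )
        )


def regularity(
    filtered_norm: np.ndarray, cfg: PipelineConfig
) -> RegularityPair | None:
    """Step/stride regularity of one walking window, or None when no
    credible periodicity is found.

    Both coefficients come from the unbiased autocorrelation normalized by
    its lag-0 value, so they are invariant to amplitude scaling and lie in
    [-1, 1].
    """
    x = np.asarray(filtered_norm, dtype=float)
    fs = cfg.sampling_rate_hz
    if np.std(x) == 0:
        return None
    ac = unbiased_autocorr(x, min(x.size - 1, int(round(2.5 * fs))))
    found = autocorr_step_peaks(ac, fs)
    if found is None:
        return None
    _, step_coef, _, stride_coef = found
    return RegularityPair(step_regularity=step_coef, stride_regularity=stride_coef)


def daily_regularity(
    frame: WindowFrame, stage1: np.ndarray, cfg: PipelineConfig
) -> tuple[float | None, float | None]:
    """Mean step/stride regularity over walking windows, as percentages.

    Aggregation policy: the plain mean over windows with a defined pair;
    windows with no autocorrelation peak are excluded, and days without any
    scored window report missing.
    """
    steps_vals, stride_vals = [], []
    for i in range(frame.n_windows):
        if stage1[i] not in WALKING_STAGE1:
            continue
        pair = regularity(frame.filtered_norm[i], cfg)
        if pair is None:
            continue
        steps_vals.append(pair.step_regularity)
        if np.isfinite(pair.stride_regularity):
            stride_vals.append(pair.stride_regularity)
    step_pct = 100.0 * float(np.mean(steps_vals)) if steps_vals else None
    stride_pct = 100.0 * float(np.mean(stride_vals)) if stride_vals else None
    return step_pct, stride_pct
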