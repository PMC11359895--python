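"""Signal conditioning: Euclidean norm, band-pass filtering and windowing.

The raw tri-axial stream (units of g) is reduced to its per-sample Euclidean
norm, band-pass filtered (5th-order Butterworth, 0.25-2.5 Hz, applied
forward-backward so step-event timing is phase-preserved) and cut into
non-overlapping 4-s windows.  Trailing samples that do not fill a window are
discarded.  Recordings whose timestamps contain gaps larger than 1.5 sample
intervals are treated as broken into segments; windows never span a break.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import signal as sps

from .config import PipelineConfig
from .errors import DataError, FilterError

__all__ = [
    "SubjectMeta",
    "RawRecording",
    "WindowFrame",
    "euclidean_norm",
    "bandpass",
    "segment_windows",
    "make_frame",
]


@dataclass(frozen=True)
class SubjectMeta:
    """Participant metadata used by the speed model and normative tables."""

    id: str
    sex: str  # "female" | "male"
    height_cm: float
    age_years: float

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if not (100 < self.height_cm < 230):
            raise ValueError(f"height_cm out of range (100, 230): {self.height_cm}")
        if self.age_years < 0:
            raise ValueError(f"age_years must be >= 0: {self.age_years}")

    @property
    def sex_code(self) -> int:
        """0 = female, 1 = male (speed-model encoding)."""
        return 1 if self.sex == "male" else 0


@dataclass
class RawRecording:
    """Timestamped tri-axial acceleration in g, plus subject metadata.

    ``time_s`` is seconds since recording start; ``start_time_of_day_h`` maps
    recording time onto clock time (bedtime reporting, day slicing).
    """

    time_s: np.ndarray
    accel: np.ndarray  # shape (n, 3), columns x, y, z, in g
    sampling_rate_hz: float
    subject: SubjectMeta | None = None
    start_time_of_day_h: float = 0.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise DataError(f"accel must have shape (n, 3), got {self.accel.shape}")
        if self.time_s.shape[0] != self.accel.shape[0]:
            raise DataError("time_s and accel lengths differ")
        if self.time_s.size > 1 and np.any(np.diff(self.time_s) <= 0):
            raise DataError("timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.accel.shape[0]

    @property
    def duration_s(self) -> float:
        if self.n_samples == 0:
            return 0.0
        return float(self.time_s[-1] - self.time_s[0]) + 1.0 / self.sampling_rate_hz


@dataclass
class WindowFrame:
    """Non-overlapping windows of conditioned signal, optionally labelled.

    All window blocks are views into contiguous per-segment arrays:
    ``filtered_norm`` and ``raw_norm`` have shape (n_windows, samples),
    ``raw_axes`` and ``filtered_axes`` shape (n_windows, samples, 3).
    ``stage1``/``stage2`` hold activity labels ("" where absent) and
    ``truth`` carries optional per-window ground-truth arrays (training).
    """

    start_times: np.ndarray
    raw_norm: np.ndarray
    filtered_norm: np.ndarray
    raw_axes: np.ndarray
    filtered_axes: np.ndarray
    sampling_rate_hz: float
    window_s: float
    subject: SubjectMeta | None = None
    stage1: np.ndarray | None = None
    stage2: np.ndarray | None = None
    truth: dict[str, Any] = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return self.start_times.shape[0]

    @property
    def samples_per_window(self) -> int:
        return self.raw_norm.shape[1]

    def __len__(self) -> int:
        return self.n_windows


def euclidean_norm(accel: np.ndarray | RawRecording) -> np.ndarray:
    """Per-sample Euclidean norm of the tri-axial signal, in g.

    Raises :class:`DataError` naming the first offending sample index when
    non-finite values are present.
    """
    arr = accel.accel if isinstance(accel, RawRecording) else np.asarray(accel, float)
    bad = ~np.isfinite(arr)
    if bad.any():
        idx = int(np.flatnonzero(bad.any(axis=1))[0])
        raise DataError(f"non-finite acceleration at sample index {idx}")
    return np.sqrt(np.einsum("ij,ij->i", arr, arr))


def _design_sos(cfg: PipelineConfig) -> np.ndarray:
    return sps.butter(
        cfg.filter_order,
        [cfg.filter_low_hz, cfg.filter_high_hz],
        btype="bandpass",
        fs=cfg.sampling_rate_hz,
        output="sos",
    )


def bandpass(stream: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    """Zero-phase Butterworth band-pass of a 1-D (or column-wise 2-D) stream.

    Forward-backward application (sosfiltfilt) doubles the effective order
    and removes phase lag; the DC component is rejected entirely.
    """
    stream = np.asarray(stream, dtype=float)
    n = stream.shape[0]
    if n <= 3 * (2 * cfg.filter_order + 1):
        raise FilterError(
            f"stream of {n} samples too short for order-{cfg.filter_order} band-pass"
        )
    sos = _design_sos(cfg)
    return sps.sosfiltfilt(sos, stream, axis=0)


def _segment_boundaries(time_s: np.ndarray, fs: float) -> list[tuple[int, int]]:
    """Split sample indices into contiguous segments at timestamp gaps."""
    if time_s.size == 0:
        return []
    dt = np.diff(time_s)
    breaks = np.flatnonzero(dt > 1.5 / fs)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks + 1, [time_s.size]))
    return list(zip(starts.tolist(), ends.tolist()))


def segment_windows(
    recording: RawRecording,
    filtered: np.ndarray,
    cfg: PipelineConfig,
    *,
    raw_norm: np.ndarray | None = None,
    filtered_axes: np.ndarray | None = None,
) -> WindowFrame:
    """Cut aligned streams into non-overlapping windows of ``cfg.window_s``.

    The trailing remainder of each contiguous segment is discarded.  A
    recording shorter than one window yields an empty frame (not an error).
    """
    if filtered.shape[0] != recording.n_samples:
        raise DataError("filtered stream not aligned with recording")
    if raw_norm is None:
        raw_norm = euclidean_norm(recording)
    if filtered_axes is None:
        filtered_axes = np.zeros_like(recording.accel)
    w = int(round(cfg.window_s * cfg.sampling_rate_hz))

    blocks_f, blocks_r, blocks_a, blocks_fa, starts = [], [], [], [], []
    for s, e in _segment_boundaries(recording.time_s, cfg.sampling_rate_hz):
        k = (e - s) // w
        if k == 0:
            continue
        sl = slice(s, s + k * w)
        blocks_f.append(filtered[sl].reshape(k, w))
        blocks_r.append(raw_norm[sl].reshape(k, w))
        blocks_a.append(recording.accel[sl].reshape(k, w, 3))
        blocks_fa.append(filtered_axes[sl].reshape(k, w, 3))
        starts.append(recording.time_s[s : s + k * w : w])

    if not starts:
        empty2 = np.zeros((0, w))
        empty3 = np.zeros((0, w, 3))
        return WindowFrame(
            start_times=np.zeros(0),
            raw_norm=empty2,
            filtered_norm=empty2,
            raw_axes=empty3,
            filtered_axes=empty3,
            sampling_rate_hz=cfg.sampling_rate_hz,
            window_s=cfg.window_s,
            subject=recording.subject,
        )
    return WindowFrame(
        start_times=np.concatenate(starts),
        raw_norm=np.concatenate(blocks_r),
        filtered_norm=np.concatenate(blocks_f),
        raw_axes=np.concatenate(blocks_a),
        filtered_axes=np.concatenate(blocks_fa),
        sampling_rate_hz=cfg.sampling_rate_hz,
        window_s=cfg.window_s,
        subject=recording.subject,
    )


def resample_to(recording: RawRecording, cfg: PipelineConfig) -> RawRecording:
    """Linearly resample a recording onto the configured uniform rate."""
    fs = cfg.sampling_rate_hz
    if abs(recording.sampling_rate_hz - fs) / fs < 0.01:
        return recording
    t_new = np.arange(recording.time_s[0], recording.time_s[-1], 1.0 / fs)
    accel = np.column_stack(
        [np.interp(t_new, recording.time_s, recording.accel[:, j]) for j in range(3)]
    )
    return RawRecording(
        time_s=t_new,
        accel=accel,
        sampling_rate_hz=fs,
        subject=recording.subject,
        start_time_of_day_h=recording.start_time_of_day_h,
    )


def make_frame(recording: RawRecording, cfg: PipelineConfig) -> WindowFrame:
    """Full conditioning chain: norm -> band-pass (norm and axes) -> windows.

    Per-axis band-passed signals are kept alongside the norm because the
    inter-axis correlation features and the speed predictors are defined on
    the movement band, where gravity no longer dominates.
    """
    recording = resample_to(recording, cfg)
    raw_norm = euclidean_norm(recording)
    w = int(round(cfg.window_s * cfg.sampling_rate_hz))
    n_filt = np.zeros_like(raw_norm)
    a_filt = np.zeros_like(recording.accel)
    for s, e in _segment_boundaries(recording.time_s, cfg.sampling_rate_hz):
        if e - s < w:
            continue
        try:
            n_filt[s:e] = bandpass(raw_norm[s:e], cfg)
            a_filt[s:e] = bandpass(recording.accel[s:e], cfg)
        except FilterError:
            continue
    return segment_windows(
        recording, n_filt, cfg, raw_norm=raw_norm, filtered_axes=a_filt
    )
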