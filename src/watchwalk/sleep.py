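"""Sleep period detection from sustained wrist-angle inactivity.

A deliberately simplified variant of the arm-angle family of algorithms:
the arm angle atan(z / sqrt(x^2 + y^2)) is computed on 5-s epoch medians of
the raw axes; runs where the successive-epoch angle change stays below 5
degrees for at least 5 minutes are sustained-inactivity blocks; blocks
separated by less than 60 minutes are joined, and the longest joined block
in the (noon-to-noon) day slice is the sleep period.  Sleep duration is the
block span; bedtime is its onset clock time.  No sleep-diary anchoring and
no multi-night harmonisation are attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .preprocess import RawRecording

__all__ = ["SleepEstimate", "estimate_sleep"]


@dataclass
class SleepEstimate:
    sleep_duration_h: float | None
    bedtime_h: float | None  # clock hour of day in [0, 24)
    sustained_inactivity_blocks: list[tuple[float, float]] = field(default_factory=list)

    @property
    def missing(self) -> bool:
        return self.sleep_duration_h is None


def _epoch_angles(recording: RawRecording, cfg: PipelineConfig) -> tuple[np.ndarray, float]:
    """Arm angle (degrees) per non-overlapping 5-s epoch of axis medians."""
    fs = recording.sampling_rate_hz
    per = int(round(cfg.sleep_epoch_s * fs))
    n_ep = recording.n_samples // per
    if n_ep == 0:
        return np.zeros(0), 0.0
    block = recording.accel[: n_ep * per].reshape(n_ep, per, 3)
    med = np.median(block, axis=1)
    angle = np.degrees(np.arctan2(med[:, 2], np.sqrt(med[:, 0] ** 2 + med[:, 1] ** 2)))
    return angle, cfg.sleep_epoch_s


def estimate_sleep(
    recording: RawRecording, cfg: PipelineConfig, min_hours: float = 12.0
) -> SleepEstimate:
    """Sleep duration and bedtime for one day slice of a recording.

    The slice must span at least ``min_hours`` of data; otherwise (or when
    no sustained-inactivity block exists) the estimate is flagged missing.
    """
    if recording.duration_s < min_hours * 3600.0 - 1.0:
        return SleepEstimate(None, None, [])
    angle, epoch_s = _epoch_angles(recording, cfg)
    if angle.size < 2:
        return SleepEstimate(None, None, [])

    quiet = np.abs(np.diff(angle)) < cfg.sleep_angle_deg
    min_epochs = int(round(cfg.sleep_min_block_min * 60.0 / epoch_s))

    # maximal runs of quiet epoch transitions
    runs: list[tuple[int, int]] = []  # [start_epoch, end_epoch) of quiet
    i = 0
    while i < quiet.size:
        if quiet[i]:
            j = i
            while j < quiet.size and quiet[j]:
                j += 1
            if (j - i + 1) >= min_epochs:
                runs.append((i, j + 1))
            i = j
        else:
            i += 1
    if not runs:
        return SleepEstimate(None, None, [])

    t0 = float(recording.time_s[0])
    blocks = [
        (t0 + s * epoch_s, t0 + e * epoch_s) for s, e in runs
    ]
    # join blocks separated by < sleep_join_gap_min into candidate periods
    join_s = cfg.sleep_join_gap_min * 60.0
    periods: list[tuple[float, float]] = [blocks[0]]
    for b in blocks[1:]:
        last = periods[-1]
        if b[0] - last[1] < join_s:
            periods[-1] = (last[0], b[1])
        else:
            periods.append(b)
    onset, offset = max(periods, key=lambda p: p[1] - p[0])
    duration_h = (offset - onset) / 3600.0
    bedtime_h = (recording.start_time_of_day_h + onset / 3600.0) % 24.0
    return SleepEstimate(
        sleep_duration_h=duration_h,
        bedtime_h=bedtime_h,
        sustained_inactivity_blocks=blocks,
    )
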