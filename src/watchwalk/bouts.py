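"""Walking-bout assembly with gap bridging and walk-length biomarkers.

A window counts as walking when its stage-1 class is arm-swing or complex
walking.  Maximal runs of consecutive walking windows form candidate bouts;
a gap between two neighbouring runs is bridged when all three criteria hold:

1. the gap does not exceed 60 s;
2. the gap does not exceed both neighbouring run durations (gap <= min);
3. the gap does not exceed one-fifth of either neighbour (gap <= max / 5).

Bridging sweeps left to right and repeats until no gap qualifies, because a
merge lengthens its neighbours and may enable further bridging.  Bridged gap
time counts toward bout duration but carries no steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .labels import WALKING_STAGE1

__all__ = [
    "WalkingBout",
    "gap_bridgeable",
    "assemble_bouts",
    "longest_walk",
    "walk_exposure_proportions",
]


@dataclass
class WalkingBout:
    start_time: float
    end_time: float
    window_indices: list[int]
    bridged_gaps: list[tuple[float, float]] = field(default_factory=list)

    @property
    def duration_s(self) -> float:
        return self.end_time - self.start_time


def gap_bridgeable(
    prev_s: float, gap_s: float, next_s: float, cfg: PipelineConfig
) -> bool:
    """Direct evaluation of the three bridging criteria on durations in s."""
    return (
        gap_s <= cfg.bridge_max_gap_s
        and gap_s <= min(prev_s, next_s)
        and gap_s <= cfg.bridge_fraction * max(prev_s, next_s)
    )


def assemble_bouts(
    stage1: np.ndarray,
    start_times: np.ndarray,
    cfg: PipelineConfig,
) -> list[WalkingBout]:
    """Group time-ordered labelled windows into bridged walking bouts."""
    stage1 = np.asarray(stage1, dtype=object)
    start_times = np.asarray(start_times, dtype=float)
    if stage1.shape != start_times.shape:
        raise ValueError("labels and start times differ in length")
    if start_times.size > 1 and np.any(np.diff(start_times) <= 0):
        raise ValueError("window start times must be strictly increasing")
    w = cfg.window_s
    walking = np.asarray([s in WALKING_STAGE1 for s in stage1], dtype=bool)
    if not walking.any():
        return []

    # maximal runs of walking windows that are also contiguous in time
    runs: list[WalkingBout] = []
    idx = np.flatnonzero(walking)
    current = [int(idx[0])]
    for i in idx[1:]:
        prev = current[-1]
        contiguous = (i == prev + 1) and (
            abs(start_times[i] - start_times[prev] - w) < 1e-6
        )
        if contiguous:
            current.append(int(i))
        else:
            runs.append(_run_to_bout(current, start_times, w))
            current = [int(i)]
    runs.append(_run_to_bout(current, start_times, w))

    # iterative left-to-right bridging until fixpoint
    changed = True
    while changed and len(runs) > 1:
        changed = False
        merged: list[WalkingBout] = [runs[0]]
        for nxt in runs[1:]:
            cur = merged[-1]
            gap = nxt.start_time - cur.end_time
            if gap_bridgeable(cur.duration_s, gap, nxt.duration_s, cfg):
                cur.bridged_gaps.append((cur.end_time, gap))
                cur.bridged_gaps.extend(nxt.bridged_gaps)
                cur.end_time = nxt.end_time
                cur.window_indices.extend(nxt.window_indices)
                changed = True
            else:
                merged.append(nxt)
        runs = merged
    return runs


def _run_to_bout(indices: list[int], start_times: np.ndarray, w: float) -> WalkingBout:
    return WalkingBout(
        start_time=float(start_times[indices[0]]),
        end_time=float(start_times[indices[-1]] + w),
        window_indices=list(indices),
    )


def longest_walk(bouts: list[WalkingBout]) -> float:
    """Duration of the longest continuous walking bout, seconds (0 if none)."""
    if not bouts:
        return 0.0
    return max(b.duration_s for b in bouts)


def walk_exposure_proportions(
    bouts: list[WalkingBout], cfg: PipelineConfig
) -> tuple[float | None, float | None]:
    """Cumulative-exposure percentages of walking time in bouts >= 8 s / 60 s.

    Returns (None, None) when there is no walking time: the marker is
    missing, not zero.
    """
    total = sum(b.duration_s for b in bouts)
    if total <= 0:
        return None, None
    ge_short = sum(b.duration_s for b in bouts if b.duration_s >= cfg.walk_threshold_short_s)
    ge_long = sum(b.duration_s for b in bouts if b.duration_s >= cfg.walk_threshold_long_s)
    return 100.0 * ge_short / total, 100.0 * ge_long / total
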