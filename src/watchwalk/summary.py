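"""Daily biomarker assembly, wear-time criteria, normative tables, z-scores.

One subject-day reduces to 21 fields (20 biomarkers plus the two composite
hand-position groups counted as one row each in reporting): sleep duration
and bedtime; steps per day; longest walk and the cumulative-exposure
percentages of walks >= 8 s / >= 60 s; maximal and usual walking speed
(cm/s); cadence median and IQR; step-time variability; step and stride
regularity; and the hand-position percentages over walking windows, with
"% static" = texting + phone call and "% adaptive" = pockets + shoulder +
briefcase.

Cohort machinery: per-day wear hours via a movement-variance non-wear
heuristic (60-min sliding blocks with all-axis SD < 13 mg), the two
inclusion criteria (>= 5 complete days; >= 3 days with >= 12 h), sex x
age-group normative percentile grids, and direction-aligned z-score
profiles against a reference cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._signal import quantile
from .config import PipelineConfig
from .labels import WALKING_STAGE1
from .preprocess import RawRecording

__all__ = [
    "DailyBiomarkers",
    "BIOMARKER_FIELDS",
    "SKEWED_MARKERS",
    "REVERSED_MARKERS",
    "hand_position_percentages",
    "wear_time",
    "summarize_day",
    "pool_subject_days",
    "normative_table",
    "zscore_profile",
]


@dataclass
class DailyBiomarkers:
    """One subject-day of the biomarker panel; None = missing with reason."""

    subject_id: str
    day: int
    sleep_duration_h: float | None = None
    bedtime_h: float | None = None
    steps_per_day: float | None = None
    longest_walk_s: float | None = None
    pct_walk_ge_8s: float | None = None
    pct_walk_ge_60s: float | None = None
    max_speed_cms: float | None = None
    usual_speed_cms: float | None = None
    cadence_median_spm: float | None = None
    cadence_iqr_spm: float | None = None
    step_time_variability_ms: float | None = None
    step_regularity_pct: float | None = None
    stride_regularity_pct: float | None = None
    pct_arm_swing: float | None = None
    pct_texting: float | None = None
    pct_phone_call: float | None = None
    pct_hands_in_pockets: float | None = None
    pct_shoulder_bag: float | None = None
    pct_briefcase: float | None = None
    pct_static: float | None = None
    pct_adaptive: float | None = None
    missing_reasons: dict | None = None

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("missing_reasons")
        return d


BIOMARKER_FIELDS: tuple[str, ...] = (
    "sleep_duration_h", "bedtime_h", "steps_per_day", "longest_walk_s",
    "pct_walk_ge_8s", "pct_walk_ge_60s", "max_speed_cms", "usual_speed_cms",
    "cadence_median_spm", "cadence_iqr_spm", "step_time_variability_ms",
    "step_regularity_pct", "stride_regularity_pct", "pct_arm_swing",
    "pct_texting", "pct_phone_call", "pct_hands_in_pockets",
    "pct_shoulder_bag", "pct_briefcase", "pct_static", "pct_adaptive",
)

#: markers summarized by median/IQR and pooled by per-subject median
SKEWED_MARKERS: frozenset[str] = frozenset(
    {
        "longest_walk_s", "pct_walk_ge_60s", "pct_arm_swing", "pct_texting",
        "pct_phone_call", "pct_hands_in_pockets", "pct_shoulder_bag",
        "pct_briefcase", "pct_static", "pct_adaptive",
    }
)

#: markers where lower values mean better performance (z-score sign flip)
REVERSED_MARKERS: frozenset[str] = frozenset({"step_time_variability_ms"})

_STAGE2_TO_FIELD = {
    "hands_in_pockets": "pct_hands_in_pockets",
    "hands_held_stationary": "pct_texting",
    "hand_next_to_ear": "pct_phone_call",
    "hand_on_shoulder": "pct_shoulder_bag",
    "briefcase_grocery_bag": "pct_briefcase",
}


def hand_position_percentages(
    stage1: np.ndarray, stage2: np.ndarray
) -> dict[str, float] | None:
    """Hand-position mix over walking windows; None when no walking window.

    Percentages over {arm swing, pockets, texting, phone, shoulder,
    briefcase} sum to 100; pct_static = texting + phone and pct_adaptive =
    pockets + shoulder + briefcase by construction.
    """
    stage1 = np.asarray(stage1, dtype=object)
    stage2 = np.asarray(stage2, dtype=object)
    walking = np.asarray([s in WALKING_STAGE1 for s in stage1], dtype=bool)
    n = int(walking.sum())
    if n == 0:
        return None
    out = {"pct_arm_swing": 100.0 * float(np.sum(stage1 == "walk_arm_swing")) / n}
    for cls, fieldname in _STAGE2_TO_FIELD.items():
        out[fieldname] = 100.0 * float(np.sum(walking & (stage2 == cls))) / n
    out["pct_static"] = out["pct_texting"] + out["pct_phone_call"]
    out["pct_adaptive"] = (
        out["pct_hands_in_pockets"] + out["pct_shoulder_bag"] + out["pct_briefcase"]
    )
    return out


# ---------------------------------------------------------------------------
# wear time


def wear_time(
    recording: RawRecording, cfg: PipelineConfig, day_length_h: float = 24.0
) -> pd.DataFrame:
    """Per-day wear hours from the movement-variance non-wear heuristic.

    Non-wear: 60-min blocks, slid in 15-min increments, whose per-axis SD is
    below 13 mg on all three axes; every 15-min tile covered by such a block
    counts as non-wear.  Days are counted from the start of the recording.
    Returns a DataFrame with columns day, wear_hours, complete
    (wear >= 23 h) and relaxed (wear >= 12 h).
    """
    fs = recording.sampling_rate_hz
    tile_s = 15 * 60.0
    per = int(round(tile_s * fs))
    n_tiles = recording.n_samples // per
    block_tiles = int(round(cfg.nonwear_block_min * 60.0 / tile_s))
    nonwear_tile = np.zeros(n_tiles, dtype=bool)
    if n_tiles >= block_tiles:
        acc = recording.accel[: n_tiles * per].reshape(n_tiles, per, 3)
        sums = acc.sum(axis=1)
        sq = (acc**2).sum(axis=1)
        # sliding 60-min block statistics from 15-min tile sums
        csum = np.cumsum(np.vstack([np.zeros(3), sums]), axis=0)
        csq = np.cumsum(np.vstack([np.zeros(3), sq]), axis=0)
        m = block_tiles * per
        for b in range(n_tiles - block_tiles + 1):
            s = csum[b + block_tiles] - csum[b]
            q = csq[b + block_tiles] - csq[b]
            var = q / m - (s / m) ** 2
            if np.all(np.sqrt(np.maximum(var, 0.0)) < cfg.nonwear_sd_g):
                nonwear_tile[b : b + block_tiles] = True

    tiles_per_day = int(round(day_length_h * 3600.0 / tile_s))
    n_days = int(np.ceil(recording.duration_s / (day_length_h * 3600.0)))
    rows = []
    for d in range(n_days):
        lo, hi = d * tiles_per_day, (d + 1) * tiles_per_day
        day_tiles = nonwear_tile[lo:min(hi, n_tiles)]
        covered_h = day_tiles.size * tile_s / 3600.0
        wear_h = covered_h - day_tiles.sum() * tile_s / 3600.0
        rows.append(
            {
                "day": d,
                "wear_hours": wear_h,
                "complete": wear_h >= cfg.weartime_full_day_hours,
                "relaxed": wear_h >= cfg.weartime_relaxed_hours,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["full_criterion"] = bool(df["complete"].sum() >= cfg.weartime_full_days)
    df.attrs["relaxed_criterion"] = bool(df["relaxed"].sum() >= cfg.weartime_relaxed_days)
    return df


# ---------------------------------------------------------------------------
# daily assembly


def summarize_day(
    subject_id: str,
    day: int,
    stage1: np.ndarray,
    stage2: np.ndarray,
    bouts,
    step_metrics,
    step_series,
    speed_predictions: np.ndarray,
    sleep_estimate,
    cfg: PipelineConfig,
) -> DailyBiomarkers:
    """Assemble one subject-day's biomarker panel from the stage outputs.

    Missingness is data, not an error: a day with no walking reports all
    gait fields missing (with reason codes) while sleep fields remain
    populated.
    """
    from .bouts import longest_walk, walk_exposure_proportions
    from .speed import daily_speeds

    out = DailyBiomarkers(subject_id=subject_id, day=day)
    reasons: dict[str, str] = {}

    if sleep_estimate is not None and not sleep_estimate.missing:
        out.sleep_duration_h = sleep_estimate.sleep_duration_h
        out.bedtime_h = sleep_estimate.bedtime_h
    else:
        reasons["sleep"] = "no sustained inactivity block"

    if bouts:
        out.longest_walk_s = longest_walk(bouts)
        p8, p60 = walk_exposure_proportions(bouts, cfg)
        out.pct_walk_ge_8s = p8
        out.pct_walk_ge_60s = p60
    else:
        reasons["bouts"] = "no walking detected"

    if step_series is not None:
        out.steps_per_day = step_series.total_steps
    if step_metrics is not None and step_metrics.cadence_median_spm is not None:
        out.cadence_median_spm = step_metrics.cadence_median_spm
        out.cadence_iqr_spm = step_metrics.cadence_iqr_spm
        out.step_time_variability_ms = step_metrics.step_time_variability_ms
    else:
        reasons["episodes"] = "no complete 8-step episode"

    mx, us = daily_speeds(speed_predictions, cfg)
    if mx is not None:
        out.max_speed_cms = 100.0 * mx
        out.usual_speed_cms = 100.0 * us
    else:
        reasons["speed"] = "no scored arm-swing window"

    hp = hand_position_percentages(stage1, stage2)
    if hp is not None:
        for k, v in hp.items():
            setattr(out, k, v)
    else:
        reasons["hand_positions"] = "no walking windows"

    out.missing_reasons = reasons
    return out


# ---------------------------------------------------------------------------
# cohort aggregation


def pool_subject_days(daily: pd.DataFrame) -> pd.DataFrame:
    """One row per subject: mean of included days (median for skewed markers)."""
    if "subject_id" not in daily.columns:
        raise ValueError("daily table must carry subject_id")
    records = []
    for sid, grp in daily.groupby("subject_id", sort=True):
        row: dict = {"subject_id": sid}
        for fieldname in BIOMARKER_FIELDS:
            if fieldname not in grp.columns:
                continue
            vals = pd.to_numeric(grp[fieldname], errors="coerce").dropna()
            if vals.empty:
                row[fieldname] = np.nan
            elif fieldname == "bedtime_h":
                # circular mean on the 24-h clock
                rad = np.asarray(vals) * 2 * np.pi / 24.0
                ang = np.arctan2(np.mean(np.sin(rad)), np.mean(np.cos(rad)))
                row[fieldname] = (ang * 24.0 / (2 * np.pi)) % 24.0
            elif fieldname in SKEWED_MARKERS:
                row[fieldname] = float(vals.median())
            else:
                row[fieldname] = float(vals.mean())
        records.append(row)
    return pd.DataFrame(records)


def _age_group(age: float, edges: tuple[float, ...]) -> str | None:
    for lo, hi in zip(edges, edges[1:]):
        if lo <= age < hi:
            return f"{int(lo)}-{int(hi) - 1}"
    return None


def normative_table(
    pooled: pd.DataFrame,
    demographics: pd.DataFrame,
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """Percentile grid per biomarker x sex x age group.

    ``demographics`` needs columns subject_id, sex, age_years.  Subjects
    whose age falls outside the age-group edges are excluded.  Empty strata
    are reported with n = 0 and missing percentiles.  Percentile columns are
    non-decreasing left to right within every row by construction.
    """
    merged = pooled.merge(demographics, on="subject_id", how="inner")
    merged["age_group"] = [
        _age_group(a, cfg.age_group_edges) for a in merged["age_years"]
    ]
    merged = merged[merged["age_group"].notna()]
    groups = [f"{int(lo)}-{int(hi) - 1}" for lo, hi in
              zip(cfg.age_group_edges, cfg.age_group_edges[1:])]
    rows = []
    pcols = [f"p{int(p) if float(p).is_integer() else p}" for p in cfg.norm_percentiles]
    for fieldname in BIOMARKER_FIELDS:
        if fieldname not in merged.columns:
            continue
        for sex in ("female", "male"):
            for ag in groups:
                sel = merged[(merged["sex"] == sex) & (merged["age_group"] == ag)]
                vals = pd.to_numeric(sel[fieldname], errors="coerce").dropna().to_numpy()
                row = {"biomarker": fieldname, "sex": sex, "age_group": ag,
                       "n": int(vals.size)}
                for p, cname in zip(cfg.norm_percentiles, pcols):
                    row[cname] = quantile(vals, p) if vals.size else np.nan
                rows.append(row)
    return pd.DataFrame(rows)


def zscore_profile(
    subject_values: pd.Series | dict,
    reference: pd.DataFrame,
) -> pd.Series:
    """Standardized biomarker profile against a reference cohort.

    z = (x - ref_mean) / ref_sd, with the sign flipped for lower-is-better
    markers so a positive score always indicates better performance.  A
    marker with zero reference SD (or missing value) scores NaN.
    """
    if isinstance(subject_values, dict):
        subject_values = pd.Series(subject_values)
    out = {}
    for fieldname in BIOMARKER_FIELDS:
        if fieldname == "bedtime_h":
            continue  # clock time has no better/worse direction
        if fieldname not in reference.columns or fieldname not in subject_values:
            continue
        ref = pd.to_numeric(reference[fieldname], errors="coerce").dropna()
        x = subject_values[fieldname]
        if ref.size < 2 or x is None or not np.isfinite(x):
            out[fieldname] = np.nan
            continue
        sd = float(ref.std(ddof=1))
        if sd == 0:
            out[fieldname] = np.nan
            continue
        z = (float(x) - float(ref.mean())) / sd
        if fieldname in REVERSED_MARKERS:
            z = -z
        out[fieldname] = z
    return pd.Series(out)
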