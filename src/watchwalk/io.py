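"""On-disk artifacts and end-to-end pipeline orchestration.

Canonical input is delimited text with header ``time,x,y,z`` (seconds, g)
plus an optional JSON metadata sidecar carrying subject sex, height, age and
the recording's start clock time.  Models persist as a directory holding a
metadata JSON and pickled weight blobs.  ``run_pipeline`` ties the stages
together per day slice: conditioning -> features -> classification -> bouts
-> steps -> speed -> sleep -> daily summary, and returns the daily biomarker
table with a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import pickle
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bouts import assemble_bouts
from .classifier import ClassifierModel, predict
from .config import PipelineConfig, save_config
from .errors import DataError
from .features import FEATURE_VERSION, extract_features
from .preprocess import RawRecording, SubjectMeta, make_frame
from .sleep import estimate_sleep
from .speed import SpeedModel, build_predictors, predict_speed
from .steps import episode_metrics, steps_in_bouts
from .summary import DailyBiomarkers, summarize_day, wear_time

__all__ = [
    "read_recording",
    "write_recording",
    "save_models",
    "load_models",
    "run_pipeline",
    "daily_table",
]

_DAY_S = 86400.0


def read_recording(
    path: str | Path,
    cfg: PipelineConfig,
    subject: SubjectMeta | None = None,
) -> RawRecording:
    """Read a delimited-text recording with header time,x,y,z.

    A JSON sidecar ``<path>.meta.json`` (if present) supplies subject
    metadata and the start clock hour.  The sampling rate is inferred from
    the timestamps; rates differing from the configured rate by more than 1%
    are accepted and resampled later in conditioning.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ("time", "x", "y", "z") if c not in df.columns]
    if missing:
        raise DataError(f"{path.name}: missing column(s) {', '.join(missing)}")
    time_s = df["time"].to_numpy(dtype=float)
    if time_s.size < 2:
        raise DataError(f"{path.name}: need at least 2 samples")
    dt = np.diff(time_s)
    fs = 1.0 / float(np.median(dt))
    start_clock = 0.0
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if subject is None and sidecar.exists():
        meta = json.loads(sidecar.read_text())
        start_clock = float(meta.get("start_time_of_day_h", 0.0))
        if {"id", "sex", "height_cm", "age_years"} <= set(meta):
            subject = SubjectMeta(
                id=str(meta["id"]),
                sex=meta["sex"],
                height_cm=float(meta["height_cm"]),
                age_years=float(meta["age_years"]),
            )
    return RawRecording(
        time_s=time_s,
        accel=df[["x", "y", "z"]].to_numpy(dtype=float),
        sampling_rate_hz=fs,
        subject=subject,
        start_time_of_day_h=start_clock,
    )


def write_recording(recording: RawRecording, path: str | Path) -> None:
    """Write a recording as time,x,y,z text plus its metadata sidecar."""
    from .simulate import write_recording_csv

    path = Path(path)
    write_recording_csv(recording, path)
    meta: dict = {"start_time_of_day_h": recording.start_time_of_day_h}
    if recording.subject is not None:
        meta.update(asdict(recording.subject))
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))


def save_models(
    classifier: ClassifierModel, speed: SpeedModel, directory: str | Path
) -> None:
    """Persist both models as metadata JSON + pickled weight blobs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "software_version": __version__,
        "feature_version": classifier.feature_version,
        "classifier": classifier.metadata,
        "speed": speed.metadata,
    }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=2))
    with open(directory / "classifier.pkl", "wb") as fh:
        pickle.dump(classifier, fh)
    with open(directory / "speed.pkl", "wb") as fh:
        pickle.dump(speed, fh)


def load_models(directory: str | Path) -> tuple[ClassifierModel, SpeedModel]:
    directory = Path(directory)
    with open(directory / "classifier.pkl", "rb") as fh:
        clf = pickle.load(fh)
    with open(directory / "speed.pkl", "rb") as fh:
        spd = pickle.load(fh)
    return clf, spd


def _slice_recording(rec: RawRecording, t_lo: float, t_hi: float) -> RawRecording:
    lo, hi = np.searchsorted(rec.time_s, [t_lo, t_hi])
    return RawRecording(
        time_s=rec.time_s[lo:hi],
        accel=rec.accel[lo:hi],
        sampling_rate_hz=rec.sampling_rate_hz,
        subject=rec.subject,
        start_time_of_day_h=rec.start_time_of_day_h,
    )


def _config_hash(cfg: PipelineConfig) -> str:
    import tempfile

    with tempfile.NamedTemporaryFile("w+", suffix=".toml") as fh:
        save_config(cfg, fh.name)
        fh.seek(0)
        return hashlib.sha256(fh.read().encode()).hexdigest()[:16]


def run_pipeline(
    recording: RawRecording,
    classifier: ClassifierModel,
    speed_model: SpeedModel,
    cfg: PipelineConfig,
) -> tuple[pd.DataFrame, dict]:
    """End-to-end daily biomarker extraction for one multi-day recording.

    Gait and wear-time days are 24-h slices from the recording start
    (recordings conventionally start at midnight); the night attributed to
    day d is searched in the noon(d) -> noon(d+1) slice so a sleep period is
    never split across calendar days.  Deterministic: identical inputs and
    models give identical tables.
    """
    if recording.subject is None:
        raise DataError("run_pipeline requires subject metadata on the recording")
    wear = wear_time(recording, cfg)
    n_days = len(wear)
    corrective_rate = classifier.corrective_rate or 0.0

    rows = []
    counts = {"windows": 0, "walking_windows": 0, "bouts": 0}
    for d in range(n_days):
        day = _slice_recording(recording, d * _DAY_S, (d + 1) * _DAY_S)
        if day.n_samples == 0:
            rows.append(DailyBiomarkers(recording.subject.id, d).as_dict())
            continue
        frame = make_frame(day, cfg)
        feats = extract_features(frame, cfg)
        stage1, stage2 = predict(classifier, frame, cfg)
        day_bouts = assemble_bouts(stage1, frame.start_times, cfg)
        series = steps_in_bouts(frame, stage1, day_bouts, cfg, corrective_rate)
        metrics = episode_metrics(series, cfg)
        X, _ = build_predictors(frame, stage1, cfg, features=feats)
        speed_pred = predict_speed(speed_model, X)
        night = _slice_recording(
            recording, d * _DAY_S + _DAY_S / 2, (d + 1) * _DAY_S + _DAY_S / 2
        )
        sleep_est = estimate_sleep(night, cfg)

        from .steps import daily_regularity

        daily = summarize_day(
            recording.subject.id, d, stage1, stage2, day_bouts, metrics,
            series, speed_pred, sleep_est, cfg,
        )
        step_pct, stride_pct = daily_regularity(frame, stage1, cfg)
        daily.step_regularity_pct = step_pct
        daily.stride_regularity_pct = stride_pct
        rows.append(daily.as_dict())
        counts["windows"] += frame.n_windows
        counts["walking_windows"] += int(
            np.sum([s in ("walk_arm_swing", "other_complex_walking") for s in stage1])
        )
        counts["bouts"] += len(day_bouts)

    table = pd.DataFrame(rows)
    table["wear_hours"] = wear["wear_hours"].to_numpy()
    table["complete_day"] = wear["complete"].to_numpy()
    manifest = {
        "software_version": __version__,
        "feature_version": FEATURE_VERSION,
        "config_hash": _config_hash(cfg),
        "subject_id": recording.subject.id,
        "n_days": n_days,
        "record_counts": counts,
        "weartime_full_criterion": wear.attrs["full_criterion"],
        "weartime_relaxed_criterion": wear.attrs["relaxed_criterion"],
        "warnings": [],
    }
    return table, manifest


def daily_table(
    records,
    classifier: ClassifierModel,
    speed_model: SpeedModel,
    cfg: PipelineConfig,
) -> tuple[pd.DataFrame, list[dict]]:
    """run_pipeline over a cohort; returns the stacked table and manifests."""
    tables, manifests = [], []
    for rec in records:
        tab, man = run_pipeline(rec.recording, classifier, speed_model, cfg)
        tables.append(tab)
        manifests.append(man)
    return pd.concat(tables, ignore_index=True), manifests
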