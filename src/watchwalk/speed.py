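"""Walking-speed estimation by RBF-kernel SVM regression.

Each arm-swing walking window contributes eight predictors: the subject's
sex and body height, the median and interquartile range of the
gravity-subtracted (static-removed) magnitude, the mean crude magnitude,
the mean step time detected within the window, and the Pearson correlations
of the band-passed x/y and x/z axes.  Windows with fewer than two detected
steps carry no mean step time and are excluded.  Training uses 10-fold
cross-validation partitioned at the participant level; the daily maximal and
usual walking speeds are the 95th percentile and the median of per-window
predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from ._folds import participant_folds
from ._signal import quantile
from .config import PipelineConfig
from .errors import TrainingError
from .features import FEATURE_NAMES, extract_features
from .preprocess import WindowFrame
from .steps import detect_steps

__all__ = [
    "PREDICTOR_NAMES",
    "SpeedModel",
    "SpeedFitResult",
    "build_predictors",
    "fit_speed",
    "predict_speed",
    "daily_speeds",
]

PREDICTOR_NAMES: tuple[str, ...] = (
    "sex_code",
    "height_cm",
    "median_static_removed_svm",
    "iqr_static_removed_svm",
    "mean_crude_svm",
    "mean_step_time_s",
    "corr_xy",
    "corr_xz",
)

_FEAT = {name: i for i, name in enumerate(FEATURE_NAMES)}


@dataclass
class SpeedModel:
    pipeline: Pipeline
    metadata: dict


@dataclass
class SpeedFitResult:
    model: SpeedModel
    oof_prediction: np.ndarray
    truth: np.ndarray
    participant_ids: np.ndarray
    fold_of_window: np.ndarray


def build_predictors(
    frame: WindowFrame,
    stage1: np.ndarray,
    cfg: PipelineConfig,
    features: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Predictor matrix for arm-swing windows with detectable steps.

    Returns ``(X, window_indices)`` where X has one row per scored window in
    ``PREDICTOR_NAMES`` order.
    """
    if frame.subject is None:
        raise TrainingError("speed predictors require subject metadata")
    if features is None:
        features = extract_features(frame, cfg)
    rows, idx = [], []
    for i in range(frame.n_windows):
        if stage1[i] != "walk_arm_swing":
            continue
        step_times = detect_steps(frame.filtered_norm[i], cfg)
        if step_times.size < 2:
            continue
        mean_step_time = float(np.mean(np.diff(step_times)))
        rows.append(
            [
                frame.subject.sex_code,
                frame.subject.height_cm,
                features[i, _FEAT["enmo_median"]],
                features[i, _FEAT["enmo_iqr"]],
                features[i, _FEAT["crude_mean"]],
                mean_step_time,
                features[i, _FEAT["corr_xy"]],
                features[i, _FEAT["corr_xz"]],
            ]
        )
        idx.append(i)
    if not rows:
        return np.zeros((0, len(PREDICTOR_NAMES))), np.zeros(0, dtype=int)
    return np.asarray(rows, dtype=float), np.asarray(idx, dtype=int)


def _make_svr(cfg: PipelineConfig) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svr",
                SVR(
                    kernel="rbf",
                    gamma=cfg.speed_gamma,
                    C=cfg.speed_cost,
                    epsilon=cfg.speed_epsilon,
                ),
            ),
        ]
    )


def fit_speed(
    frames: Sequence[WindowFrame],
    cfg: PipelineConfig,
    seed: int,
    n_folds: int = 10,
) -> SpeedFitResult:
    """Fit the speed regressor on labelled frames with ground-truth speeds.

    Frames must carry stage-1 labels and per-window true speed in
    ``frame.truth["speed_ms"]``.  Out-of-fold predictions are returned for
    MAPE / R-squared evaluation against the ground truth.
    """
    X_parts, y_parts, pid_parts, t_parts = [], [], [], []
    for frame in frames:
        if frame.stage1 is None or "speed_ms" not in frame.truth:
            raise TrainingError(
                "speed training frames need stage-1 labels and true window speeds"
            )
        X, idx = build_predictors(frame, frame.stage1, cfg)
        if idx.size == 0:
            continue
        y = np.asarray(frame.truth["speed_ms"], dtype=float)[idx]
        keep = np.isfinite(y)
        X_parts.append(X[keep])
        y_parts.append(y[keep])
        pid_parts.append(np.full(int(keep.sum()), frame.subject.id, dtype=object))
        t_parts.append(frame.start_times[idx][keep])
    if not X_parts:
        raise TrainingError("no arm-swing windows with known speed available")
    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)
    pids = np.concatenate(pid_parts)
    times = np.concatenate(t_parts)
    order = np.lexsort((times, pids.astype(str)))
    X, y, pids = X[order], y[order], pids[order]

    folds = participant_folds(pids, n_folds, seed)
    oof = np.empty_like(y)
    for f in np.unique(folds):
        tr, te = folds != f, folds == f
        m = _make_svr(cfg)
        m.fit(X[tr], y[tr])
        oof[te] = m.predict(X[te])

    final = _make_svr(cfg)
    final.fit(X, y)
    model = SpeedModel(
        pipeline=final,
        metadata={
            "gamma": cfg.speed_gamma,
            "C": cfg.speed_cost,
            "epsilon": cfg.speed_epsilon,
            "n_folds": int(np.unique(folds).size),
            "seed": int(seed),
            "n_windows": int(y.size),
            "predictors": list(PREDICTOR_NAMES),
        },
    )
    return SpeedFitResult(
        model=model,
        oof_prediction=oof,
        truth=y,
        participant_ids=pids,
        fold_of_window=folds,
    )


def predict_speed(model: SpeedModel, predictors: np.ndarray) -> np.ndarray:
    """Per-window speed predictions (m/s) from a predictor matrix."""
    if predictors.shape[0] == 0:
        return np.zeros(0)
    if predictors.shape[1] != len(PREDICTOR_NAMES):
        raise ValueError(
            f"expected {len(PREDICTOR_NAMES)} predictors, got {predictors.shape[1]}"
        )
    return model.pipeline.predict(predictors)


def daily_speeds(
    predictions: np.ndarray, cfg: PipelineConfig
) -> tuple[float | None, float | None]:
    """(maximal, usual) walking speed: 95th percentile and median of the
    day's per-window predictions; missing when no window was scored."""
    preds = np.asarray(predictions, dtype=float)
    preds = preds[np.isfinite(preds)]
    if preds.size == 0:
        return None, None
    return quantile(preds, cfg.speed_max_percentile), quantile(preds, 50)
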