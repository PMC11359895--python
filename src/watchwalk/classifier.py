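"""Two-stage multiclass SVM activity classification of 4-s windows.

Stage 1 assigns one of six activity classes with RBF-kernel SVMs
(gamma = 1/54, class weights [50, 25, 10, 5, 5, 5] emphasising walking);
stage 2 resolves "other complex walking" windows into five hand positions
with uniform weights.  Features are z-scaled (fitted on training folds only)
before the kernel, since a fixed gamma is only meaningful on commensurate
feature scales.  Cross-validation is 10-fold at the participant level: all
windows of a participant share one fold.  libsvm's native one-vs-one
decomposition is used, with the class weights applied per binary problem.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._folds import participant_folds
from .config import PipelineConfig
from .errors import CompatibilityError, TrainingError
from .features import FEATURE_VERSION, extract_features
from .labels import STAGE1_CLASSES, STAGE2_CLASSES
from .preprocess import WindowFrame

__all__ = ["ClassifierModel", "TrainResult", "train", "predict", "confusion_matrix"]


@dataclass
class ClassifierModel:
    """Fitted two-stage window classifier plus training metadata."""

    stage1: Pipeline
    stage2: Pipeline | None
    feature_version: str
    metadata: dict

    @property
    def corrective_rate(self) -> float | None:
        """Mean true steps per unspecified-arms-walking window (step correction)."""
        return self.metadata.get("corrective_rate")


@dataclass
class TrainResult:
    model: ClassifierModel
    fold_of_window: np.ndarray
    oof_stage1: np.ndarray
    oof_stage2: np.ndarray
    truth_stage1: np.ndarray
    truth_stage2: np.ndarray
    participant_ids: np.ndarray


def _make_stage1(cfg: PipelineConfig) -> Pipeline:
    weights = {
        cls: w for cls, w in zip(STAGE1_CLASSES, cfg.stage1_class_weights)
    }
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svm",
                SVC(
                    kernel="rbf",
                    gamma=cfg.svm_gamma,
                    C=cfg.svm_cost,
                    class_weight=weights,
                ),
            ),
        ]
    )


def _make_stage2(cfg: PipelineConfig) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="rbf", gamma=cfg.svm_gamma, C=cfg.svm_cost)),
        ]
    )


def _gather(frames: Sequence[WindowFrame], cfg: PipelineConfig):
    """Stack features/labels from labelled frames in canonical row order."""
    X_parts, s1_parts, s2_parts, pid_parts, t_parts, steps_parts = [], [], [], [], [], []
    for frame in frames:
        if frame.stage1 is None:
            raise TrainingError("training frames must carry stage-1 labels")
        if frame.subject is None:
            raise TrainingError("training frames must carry subject metadata")
        X_parts.append(extract_features(frame, cfg))
        s1_parts.append(np.asarray(frame.stage1, dtype=object))
        s2 = frame.stage2 if frame.stage2 is not None else np.full(len(frame), "", object)
        s2_parts.append(np.asarray(s2, dtype=object))
        pid_parts.append(np.full(len(frame), frame.subject.id, dtype=object))
        t_parts.append(frame.start_times)
        sc = frame.truth.get("step_count")
        steps_parts.append(
            np.asarray(sc, float) if sc is not None else np.full(len(frame), np.nan)
        )
    X = np.vstack(X_parts)
    s1 = np.concatenate(s1_parts)
    s2 = np.concatenate(s2_parts)
    pids = np.concatenate(pid_parts)
    times = np.concatenate(t_parts)
    steps = np.concatenate(steps_parts)
    # canonical order: row permutation of the input must not change anything
    order = np.lexsort((times, pids.astype(str)))
    return X[order], s1[order], s2[order], pids[order], steps[order]


def train(
    frames: Sequence[WindowFrame],
    cfg: PipelineConfig,
    seed: int,
    n_folds: int = 10,
) -> TrainResult:
    """Fit the two-stage classifier with participant-level 10-fold CV.

    Returns the final model (fitted on all data) together with out-of-fold
    predictions for unbiased confusion matrices.  The corrective step rate
    (mean ground-truth steps per unspecified-arms-walking window) is stored
    in the model metadata when the frames carry ground-truth step counts.
    """
    X, s1, s2, pids, steps = _gather(frames, cfg)
    present = set(s1.tolist())
    missing = [c for c in STAGE1_CLASSES if c not in present]
    if missing:
        raise TrainingError(f"stage-1 class absent from training data: {missing[0]}")

    folds = participant_folds(pids, n_folds, seed)
    oof1 = np.empty_like(s1)
    oof2 = np.full_like(s2, "")
    is_complex = s1 == "other_complex_walking"
    for f in np.unique(folds):
        tr, te = folds != f, folds == f
        m1 = _make_stage1(cfg)
        m1.fit(X[tr], s1[tr].astype(str))
        pred1 = m1.predict(X[te]).astype(object)
        oof1[te] = pred1
        tr2 = tr & is_complex
        if np.unique(s2[tr2]).size >= 2:
            m2 = _make_stage2(cfg)
            m2.fit(X[tr2], s2[tr2].astype(str))
            need2 = te & (oof1 == "other_complex_walking")
            if need2.any():
                oof2[need2] = m2.predict(X[need2]).astype(object)

    stage1 = _make_stage1(cfg)
    stage1.fit(X, s1.astype(str))
    stage2 = None
    if np.unique(s2[is_complex]).size >= 2:
        stage2 = _make_stage2(cfg)
        stage2.fit(X[is_complex], s2[is_complex].astype(str))

    corrective_rate = None
    unspec = s1 == "unspecified_arms_walking"
    if unspec.any() and np.isfinite(steps[unspec]).all():
        corrective_rate = float(steps[unspec].mean())

    model = ClassifierModel(
        stage1=stage1,
        stage2=stage2,
        feature_version=FEATURE_VERSION,
        metadata={
            "gamma": cfg.svm_gamma,
            "C": cfg.svm_cost,
            "stage1_class_weights": list(cfg.stage1_class_weights),
            "n_folds": int(np.unique(folds).size),
            "seed": int(seed),
            "n_windows": int(X.shape[0]),
            "n_participants": int(np.unique(pids).size),
            "corrective_rate": corrective_rate,
        },
    )
    return TrainResult(
        model=model,
        fold_of_window=folds,
        oof_stage1=oof1,
        oof_stage2=oof2,
        truth_stage1=s1,
        truth_stage2=s2,
        participant_ids=pids,
    )


def predict(
    model: ClassifierModel, frame: WindowFrame, cfg: PipelineConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Label every window: stage-1 class, and hand position where complex.

    Returns ``(stage1, stage2)`` object arrays; stage2 is "" except for
    windows classified other_complex_walking.
    """
    if model.feature_version != FEATURE_VERSION:
        raise CompatibilityError(
            f"model feature version {model.feature_version} != {FEATURE_VERSION}"
        )
    if frame.n_windows == 0:
        return np.zeros(0, dtype=object), np.zeros(0, dtype=object)
    X = extract_features(frame, cfg)
    s1 = model.stage1.predict(X).astype(object)
    s2 = np.full(s1.shape, "", dtype=object)
    mask = s1 == "other_complex_walking"
    if mask.any() and model.stage2 is not None:
        s2[mask] = model.stage2.predict(X[mask]).astype(object)
    return s1, s2


def confusion_matrix(
    truth: Sequence[str], predicted: Sequence[str], classes: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Confusion matrix (rows = truth, columns = predicted) plus per-class
    sensitivity (row-normalized diagonal), precision (column-normalized) and
    specificity."""
    truth = np.asarray(truth, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if truth.size == 0:
        raise ValueError("empty label sequences")
    if truth.shape != predicted.shape:
        raise ValueError("label sequences differ in length")
    if classes is None:
        known = set(STAGE1_CLASSES) | set(STAGE2_CLASSES)
        observed = set(truth.tolist()) | set(predicted.tolist())
        bad = observed - known
        if bad:
            raise ValueError(f"labels outside taxonomy: {sorted(bad)}")
        classes = [c for c in (*STAGE1_CLASSES, *STAGE2_CLASSES) if c in observed]
    idx = {c: i for i, c in enumerate(classes)}
    mat = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(truth, predicted):
        mat[idx[t], idx[p]] += 1
    cm = pd.DataFrame(mat, index=list(classes), columns=list(classes))
    total = mat.sum()
    diag = np.diag(mat)
    row = mat.sum(axis=1)
    colsum = mat.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sens = np.where(row > 0, diag / row, np.nan)
        prec = np.where(colsum > 0, diag / colsum, np.nan)
        tn = total - row - colsum + diag
        spec = np.where((total - row) > 0, tn / (total - row), np.nan)
    metrics = pd.DataFrame(
        {"sensitivity": sens, "precision": prec, "specificity": spec},
        index=list(classes),
    )
    return cm, metrics
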