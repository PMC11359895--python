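"""Participant-level fold assignment shared by both SVM stages."""

from __future__ import annotations

import numpy as np

from .errors import TrainingError

__all__ = ["participant_folds"]


def participant_folds(
    participant_ids: np.ndarray, n_folds: int, seed: int
) -> np.ndarray:
    """Per-row fold indices that never split one participant across folds.

    Unique participants are sorted, shuffled by a seeded RNG and dealt
    round-robin into ``min(n_folds, n_participants)`` folds, so the
    assignment depends only on the set of participants and the seed, never
    on row order.
    """
    ids = np.asarray(participant_ids)
    uniq = np.unique(ids)
    if uniq.size < 2:
        raise TrainingError(
            "participant-level cross-validation needs at least 2 participants, "
            f"got {uniq.size}"
        )
    rng = np.random.default_rng(seed)
    order = uniq[rng.permutation(uniq.size)]
    k = min(n_folds, uniq.size)
    fold_of = {pid: i % k for i, pid in enumerate(order)}
    return np.asarray([fold_of[p] for p in ids], dtype=int)
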