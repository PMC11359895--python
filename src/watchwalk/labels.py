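"""Activity label taxonomy for the two-stage window classifier.

Stage 1 assigns each 4-s window one of six activity classes; windows in the
"other complex walking" class are further resolved by stage 2 into one of
five hand positions.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "STAGE1_CLASSES",
    "STAGE2_CLASSES",
    "WALKING_STAGE1",
    "ActivityLabel",
]

STAGE1_CLASSES: tuple[str, ...] = (
    "walk_arm_swing",
    "other_complex_walking",
    "running",
    "stationary",
    "unspecified_arms_sit_stand",
    "unspecified_arms_walking",
)

STAGE2_CLASSES: tuple[str, ...] = (
    "hands_in_pockets",
    "hands_held_stationary",  # texting
    "hand_next_to_ear",       # phone call
    "hand_on_shoulder",       # shoulder bag
    "briefcase_grocery_bag",
)

#: stage-1 classes that count as walking for bout assembly and hand-position
#: percentages (unspecified arm movement while walking is credited to the
#: step count via the corrective factor only).
WALKING_STAGE1: frozenset[str] = frozenset({"walk_arm_swing", "other_complex_walking"})


@dataclass(frozen=True)
class ActivityLabel:
    """A stage-1 class plus, for complex walking only, a stage-2 hand position."""

    stage1: str
    stage2: str | None = None

    def __post_init__(self) -> None:
        if self.stage1 not in STAGE1_CLASSES:
            raise ValueError(f"unknown stage-1 class: {self.stage1!r}")
        if self.stage1 == "other_complex_walking":
            if self.stage2 not in STAGE2_CLASSES:
                raise ValueError(
                    "other_complex_walking requires a stage-2 hand position, "
                    f"got {self.stage2!r}"
                )
        elif self.stage2 is not None:
            raise ValueError(
                f"stage-2 label only valid for other_complex_walking, "
                f"got stage1={self.stage1!r}, stage2={self.stage2!r}"
            )

    @property
    def is_walking(self) -> bool:
        return self.stage1 in WALKING_STAGE1
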