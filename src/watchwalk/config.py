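"""Pipeline configuration.

Every fixed constant of the pipeline lives in :class:`PipelineConfig` so that
all stages share a single auditable parameter surface.  Configuration files
are plain-text TOML ``key = value`` pairs; unknown keys are rejected so typos
cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigError

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable constants of the biomarker pipeline.

    Units are embedded in the field names (``_hz``, ``_s``, ``_g`` ...).
    """

    # signal conditioning
    sampling_rate_hz: float = 100.0
    filter_order: int = 5
    filter_low_hz: float = 0.25
    filter_high_hz: float = 2.5
    window_s: float = 4.0

    # classification
    n_features: int = 54
    svm_gamma: float = 1.0 / 54.0
    stage1_class_weights: tuple[float, ...] = (50.0, 25.0, 10.0, 5.0, 5.0, 5.0)
    svm_cost: float = 1.0

    # bout assembly
    bridge_max_gap_s: float = 60.0
    bridge_fraction: float = 1.0 / 5.0
    walk_threshold_short_s: float = 8.0
    walk_threshold_long_s: float = 60.0

    # step metrics
    episode_steps: int = 8
    variability_percentile: float = 95.0

    # speed
    speed_max_percentile: float = 95.0
    speed_gamma: float = 1.0 / 8.0
    speed_cost: float = 1.0
    speed_epsilon: float = 0.01

    # wear time / inclusion
    weartime_full_days: int = 5
    weartime_full_day_hours: float = 23.0
    weartime_relaxed_days: int = 3
    weartime_relaxed_hours: float = 12.0
    nonwear_sd_g: float = 0.013
    nonwear_block_min: float = 60.0

    # sleep heuristic
    sleep_epoch_s: float = 5.0
    sleep_angle_deg: float = 5.0
    sleep_min_block_min: float = 5.0
    sleep_join_gap_min: float = 60.0

    # normative tables
    norm_percentiles: tuple[float, ...] = (5.0, 10.0, 25.0, 50.0, 75.0, 90.0, 95.0)
    age_group_edges: tuple[float, ...] = (45.0, 55.0, 65.0, 75.0, 80.0)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0 < self.filter_low_hz < self.filter_high_hz < self.sampling_rate_hz / 2):
            raise ConfigError(
                "filter_low_hz/filter_high_hz: need "
                "0 < low < high < sampling_rate_hz/2, got "
                f"low={self.filter_low_hz}, high={self.filter_high_hz}, "
                f"fs={self.sampling_rate_hz}"
            )
        if self.n_features != 54:
            raise ConfigError(f"n_features: must be 54, got {self.n_features}")
        if abs(self.svm_gamma - 1.0 / self.n_features) > 1e-12:
            raise ConfigError(
                f"svm_gamma: must equal 1/n_features = {1.0 / self.n_features}, "
                f"got {self.svm_gamma}"
            )
        w = self.stage1_class_weights
        if len(w) != 6 or any(x <= 0 for x in w):
            raise ConfigError(
                f"stage1_class_weights: need exactly 6 positive entries, got {w!r}"
            )
        p = self.norm_percentiles
        if any(not (0 < x < 100) for x in p) or any(a >= b for a, b in zip(p, p[1:])):
            raise ConfigError(
                f"norm_percentiles: must be strictly increasing in (0, 100), got {p!r}"
            )
        e = self.age_group_edges
        if len(e) < 2 or any(a >= b for a, b in zip(e, e[1:])):
            raise ConfigError(f"age_group_edges: must be strictly increasing, got {e!r}")
        for name in ("window_s", "bridge_max_gap_s", "episode_steps", "svm_cost"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name}: must be positive")


_FIELDS = {f.name: f for f in dataclasses.fields(PipelineConfig)}


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a :class:`PipelineConfig`, or the defaults when *path* is None.

    Raises :class:`ConfigError` on unknown keys, parse failures (naming the
    line) or invariant violations (naming the field).
    """
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    try:
        raw = tomllib.loads(text)
    except tomllib.TOMLDecodeError as exc:
        lineno = getattr(exc, "lineno", None)
        where = f" at line {lineno}" if lineno is not None else ""
        raise ConfigError(f"cannot parse {path}{where}: {exc}") from exc
    unknown = sorted(set(raw) - set(_FIELDS))
    if unknown:
        raise ConfigError(f"unknown configuration keys: {', '.join(unknown)}")
    kwargs = {}
    for key, value in raw.items():
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return PipelineConfig(**kwargs)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Serialize *cfg* as TOML key = value text (round-trips via load_config)."""
    lines = []
    for f in dataclasses.fields(cfg):
        value = getattr(cfg, f.name)
        if isinstance(value, tuple):
            rendered = "[" + ", ".join(repr(float(v)) for v in value) + "]"
        elif isinstance(value, bool):
            rendered = "true" if value else "false"
        else:
            rendered = repr(value)
        lines.append(f"{f.name} = {rendered}")
    Path(path).write_text("\n".join(lines) + "\n")
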