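"""Synthetic wrist accelerometry with scripted activities and ground truth.

Real free-living wrist recordings (and the laboratory development data) are
access-restricted, so every test and demonstration in this package runs on
synthetic signals with complete ground truth: per-sample activity labels,
step-event times, per-entry true walking speed and scripted sleep intervals.

The generative model is deliberately simple but gives each activity class a
genuinely separable signature:

* walking/running produce a quasi-periodic waveform whose phase advances by
  2*pi per step; step times follow the scheduled cadence with Gaussian
  step-time jitter.  Each hand-position class has its own oscillation
  amplitude, axis-direction mix, axis phase offsets and harmonic content
  (arm swing largest; texting/phone strongly damped).
* a small half-frequency (stride-period) component with per-class weight
  breaks the perfect step-level symmetry so stride regularity is a distinct
  quantity from step regularity.
* true walking speed enters the signal through a documented monotone map:
  the oscillation amplitude is scaled by ``0.4 + 0.6 * speed`` and, in the
  cohort generator, cadence follows ``60 + 35 * speed`` (speed in m/s), so
  speed regression has a learnable target.
* stationary wear produces gravity plus low-amplitude tissue noise; sleep a
  stable tilted orientation; "nonwear" a nearly dead channel that trips the
  non-wear detector.

Ground-truth step counts are invariant to the noise seed: the number of
steps in an entry is fixed by its cadence and duration, and only the jitter
displaces individual step times.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .errors import ScheduleError
from .preprocess import RawRecording, SubjectMeta, WindowFrame, make_frame

__all__ = [
    "ScheduleEntry",
    "ActivitySchedule",
    "GroundTruth",
    "CohortRecord",
    "ACTIVITIES",
    "synthesize_recording",
    "synthesize_cohort",
    "synthesize_development_cohort",
    "development_schedule",
    "daily_schedule",
    "labelled_frame",
    "window_truth",
    "two_way_matrix",
    "icc_theoretical",
    "sigma_subject_for_icc",
    "subject_usual_speed",
    "cadence_for_speed",
    "write_recording_csv",
    "write_ground_truth_json",
]

# ---------------------------------------------------------------------------
# activity taxonomy of the generator

#: activity -> (stage-1 class, stage-2 class or None)
ACTIVITIES: dict[str, tuple[str, str | None]] = {
    "walk_arm_swing": ("walk_arm_swing", None),
    "walk_pockets": ("other_complex_walking", "hands_in_pockets"),
    "walk_texting": ("other_complex_walking", "hands_held_stationary"),
    "walk_phone": ("other_complex_walking", "hand_next_to_ear"),
    "walk_shoulder": ("other_complex_walking", "hand_on_shoulder"),
    "walk_briefcase": ("other_complex_walking", "briefcase_grocery_bag"),
    "running": ("running", None),
    "stationary": ("stationary", None),
    "sleep": ("stationary", None),
    "nonwear": ("stationary", None),
    "unspecified_arms_sit_stand": ("unspecified_arms_sit_stand", None),
    "unspecified_arms_walking": ("unspecified_arms_walking", None),
}

STEPPED = frozenset(
    {
        "walk_arm_swing", "walk_pockets", "walk_texting", "walk_phone",
        "walk_shoulder", "walk_briefcase", "running", "unspecified_arms_walking",
    }
)

# per-class waveform parameters:
#   amp: oscillation amplitude at 1.0 m/s (g); dir: axis mixing of the
#   fundamental; psi: x/y phase offsets (rad); harm: 2nd-harmonic weight;
#   stride: half-frequency (stride) weight; noise: broadband sd (g)
_WAVE = {
    "walk_arm_swing": dict(amp=0.40, dir=(0.85, 0.30, 0.60), psi=(0.0, 1.57), harm=0.30, stride=0.15, noise=0.020),
    "walk_pockets": dict(amp=0.20, dir=(0.20, 0.55, 0.60), psi=(1.05, 0.79), harm=0.20, stride=0.12, noise=0.020),
    "walk_texting": dict(amp=0.08, dir=(0.15, 0.10, 0.60), psi=(1.57, 0.00), harm=0.50, stride=0.10, noise=0.015),
    "walk_phone": dict(amp=0.12, dir=(0.45, 0.10, 0.60), psi=(0.79, 1.57), harm=0.15, stride=0.10, noise=0.015),
    "walk_shoulder": dict(amp=0.16, dir=(0.15, 0.50, 0.60), psi=(2.09, 0.52), harm=0.40, stride=0.12, noise=0.018),
    "walk_briefcase": dict(amp=0.26, dir=(0.55, 0.25, 0.60), psi=(0.52, 1.05), harm=0.25, stride=0.14, noise=0.020),
    "running": dict(amp=0.80, dir=(0.80, 0.50, 0.80), psi=(0.0, 1.57), harm=0.30, stride=0.10, noise=0.040),
    "unspecified_arms_walking": dict(amp=0.18, dir=(0.50, 0.50, 0.60), psi=(0.3, 2.2), harm=0.20, stride=0.10, noise=0.080),
}

_NOISE_ONLY = {
    "stationary": 0.018,
    "sleep": 0.015,
    "nonwear": 0.001,
    "unspecified_arms_sit_stand": 0.150,
}

#: documented monotone speed -> amplitude coupling
def _amp_scale(speed_ms: float) -> float:
    return 0.4 + 0.6 * speed_ms


def cadence_for_speed(speed_ms: float) -> float:
    """Cohort cadence model: steps/min as a monotone function of speed (m/s)."""
    return 60.0 + 35.0 * speed_ms


# ---------------------------------------------------------------------------
# schedule and ground truth containers


@dataclass(frozen=True)
class ScheduleEntry:
    start_s: float
    duration_s: float
    activity: str
    cadence_spm: float | None = None
    speed_ms: float | None = None
    step_time_jitter_ms: float | None = None

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITIES:
            raise ScheduleError(f"unknown activity {self.activity!r}")
        if self.duration_s <= 0:
            raise ScheduleError("entry duration must be positive")
        if self.activity in STEPPED:
            if self.cadence_spm is None and self.speed_ms is None:
                raise ScheduleError(
                    f"{self.activity}: walking/running entries need cadence or speed"
                )
        elif self.cadence_spm is not None or self.speed_ms is not None:
            raise ScheduleError(
                f"{self.activity}: cadence/speed only valid for walking/running"
            )

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


ActivitySchedule = list[ScheduleEntry]


@dataclass
class GroundTruth:
    """Complete per-sample truth for one synthetic recording."""

    activity_codes: np.ndarray       # int8 per sample, index into activity_names
    activity_names: tuple[str, ...]
    step_times: np.ndarray           # strictly increasing, seconds
    speed_ms: np.ndarray             # per-sample true speed, NaN outside gait
    sleep_intervals: list[tuple[float, float]]

    def sample_activity(self) -> np.ndarray:
        names = np.asarray(self.activity_names, dtype=object)
        return names[self.activity_codes]


@dataclass
class CohortRecord:
    recording: RawRecording
    ground_truth: GroundTruth
    subject: SubjectMeta


def _validate_schedule(schedule: ActivitySchedule) -> None:
    if not schedule:
        raise ScheduleError("schedule is empty")
    entries = sorted(schedule, key=lambda e: e.start_s)
    for a, b in zip(entries, entries[1:]):
        if b.start_s < a.end_s - 1e-9:
            raise ScheduleError(
                f"entries overlap: {a.activity} ending {a.end_s:.1f}s vs "
                f"{b.activity} starting {b.start_s:.1f}s"
            )


def _entry_steps(entry: ScheduleEntry, rng: np.random.Generator) -> np.ndarray:
    """Step-event times: count fixed by cadence x duration, jitter from rng.

    Jitter perturbs each step interval (random-walk timing), so the SD of
    consecutive step intervals equals the scheduled jitter.
    """
    cadence = entry.cadence_spm
    if cadence is None:
        cadence = cadence_for_speed(entry.speed_ms)
    T = 60.0 / cadence
    n = int(np.floor(entry.duration_s / T))
    if n == 0:
        return np.zeros(0)
    jitter_ms = entry.step_time_jitter_ms if entry.step_time_jitter_ms is not None else 15.0
    intervals = np.full(n, T)
    if jitter_ms > 0:
        intervals = np.maximum(
            T + rng.normal(0.0, jitter_ms / 1000.0, n), 0.25 * T
        )
    t = entry.start_s + 0.5 * T + np.concatenate(([0.0], np.cumsum(intervals[1:])))
    # keep strictly increasing and inside the entry
    t = np.clip(t, entry.start_s + 1e-3, entry.end_s - 1e-3)
    t = np.maximum.accumulate(t + np.arange(n) * 1e-9)
    return t


def _gravity_drift(
    m: int, fs: float, rng: np.random.Generator,
    base_theta_deg: float, step_sd_deg: float, anchor_s: float = 5.0,
) -> np.ndarray:
    """Slowly wandering gravity direction (m samples, unit vectors).

    Polar and azimuth angles follow mean-reverting AR(1) walks anchored
    every ``anchor_s`` seconds, emulating how a worn wrist keeps changing
    posture during wake (the sleep detector keys on the absence of exactly
    this wander).
    """
    n_anchor = max(int(np.ceil(m / (anchor_s * fs))) + 1, 2)
    theta = np.empty(n_anchor)
    phi = np.empty(n_anchor)
    theta[0] = np.deg2rad(base_theta_deg) + rng.normal(0, np.deg2rad(step_sd_deg))
    phi[0] = rng.uniform(0, 2 * np.pi)
    for k in range(1, n_anchor):
        theta[k] = (
            0.8 * (theta[k - 1] - np.deg2rad(base_theta_deg))
            + np.deg2rad(base_theta_deg)
            + rng.normal(0, np.deg2rad(step_sd_deg))
        )
        phi[k] = phi[k - 1] + rng.normal(0, 1.5 * np.deg2rad(step_sd_deg))
    idx = np.linspace(0.0, n_anchor - 1.0, m)
    th = np.interp(idx, np.arange(n_anchor), theta)
    ph = np.interp(idx, np.arange(n_anchor), phi)
    g = np.column_stack(
        [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
    )
    return g


def synthesize_recording(
    schedule: ActivitySchedule,
    subject: SubjectMeta,
    seed: int,
    cfg: PipelineConfig | None = None,
    start_time_of_day_h: float = 0.0,
    noise_scale: float = 1.0,
) -> tuple[RawRecording, GroundTruth]:
    """Render an activity schedule into a tri-axial recording plus truth.

    Identical schedule, subject and seed give bit-identical output.  Samples
    cover [0, end of last entry); unscheduled gaps are filled with quiet
    stationary wear.  ``noise_scale`` multiplies every stochastic component
    (sensor noise, arm wobble, posture drift); 0 renders a noise-free signal
    in which only the scheduled gait waveform remains.
    """
    if cfg is None:
        cfg = PipelineConfig()
    _validate_schedule(schedule)
    entries = sorted(schedule, key=lambda e: e.start_s)
    fs = cfg.sampling_rate_hz
    t_end = entries[-1].end_s
    n = int(round(t_end * fs))
    time_s = np.arange(n) / fs
    accel = np.zeros((n, 3))
    accel[:, 2] = 1.0  # upright gravity default
    names = tuple(ACTIVITIES)
    code_of = {a: i for i, a in enumerate(names)}
    codes = np.full(n, code_of["stationary"], dtype=np.int8)
    speed = np.full(n, np.nan)
    rng = np.random.default_rng(seed)

    # baseline tissue noise everywhere (gaps = quiet stationary wear)
    accel += rng.normal(0.0, _NOISE_ONLY["stationary"], (n, 3)) * noise_scale

    all_steps: list[np.ndarray] = []
    sleep_intervals: list[tuple[float, float]] = []
    for entry in entries:
        i0 = int(round(entry.start_s * fs))
        i1 = min(int(round(entry.end_s * fs)), n)
        if i1 <= i0:
            continue
        m = i1 - i0
        codes[i0:i1] = code_of[entry.activity]
        t_local = time_s[i0:i1]

        # wandering wrist posture during wake; stable orientation in sleep
        gvec = None
        if entry.activity not in ("sleep", "nonwear"):
            gvec = _gravity_drift(m, fs, rng, base_theta_deg=30.0,
                                  step_sd_deg=8.0 * noise_scale)
            accel[i0:i1] += gvec - np.array([0.0, 0.0, 1.0])

        if entry.activity in STEPPED:
            steps = _entry_steps(entry, rng)
            all_steps.append(steps)
            spd = entry.speed_ms
            if spd is None:
                cad = entry.cadence_spm
                spd = max((cad - 60.0) / 35.0, 0.3)
            speed[i0:i1] = spd
            p = _WAVE[entry.activity]
            amp = p["amp"] * _amp_scale(spd)
            # phase advances 2*pi per step; linear extension at the edges
            T = 60.0 / (entry.cadence_spm or cadence_for_speed(spd))
            if steps.size >= 2:
                anchors_t = np.concatenate(([entry.start_s], steps, [entry.end_s]))
                ph0 = -2 * np.pi * (steps[0] - entry.start_s) / T
                ph1 = 2 * np.pi * (steps.size - 1 + (entry.end_s - steps[-1]) / T)
                anchors_p = np.concatenate(([ph0], 2 * np.pi * np.arange(steps.size), [ph1]))
                phase = np.interp(t_local, anchors_t, anchors_p)
            else:
                phase = 2 * np.pi * (t_local - entry.start_s) / T
            dx, dy, dz = p["dir"]
            px, py = p["psi"]
            harm = p["harm"] * np.sin(2 * phase)
            stride = p["stride"] * np.sin(0.5 * phase + 0.7)
            # the impact component acts along the current gravity direction,
            # so the norm oscillation amplitude is posture-independent
            radial = amp * dz * (np.sin(phase) + harm + stride)
            accel[i0:i1] += gvec * radial[:, None]
            accel[i0:i1, 0] += amp * dx * (np.sin(phase + px) + 0.5 * harm + stride)
            accel[i0:i1, 1] += amp * dy * (np.sin(phase + py) + 0.5 * harm)
            extra = (p["noise"] - _NOISE_ONLY["stationary"]) * noise_scale
            if extra > 0:
                accel[i0:i1] += rng.normal(0.0, extra, (m, 3))
            if entry.activity == "unspecified_arms_walking":
                # erratic low-frequency arm use on top of gait
                wob = rng.normal(0.0, 1.0, (m // 25 + 2, 3))
                idx = np.linspace(0, wob.shape[0] - 1, m)
                for j in range(3):
                    accel[i0:i1, j] += 0.10 * noise_scale * np.interp(
                        idx, np.arange(wob.shape[0]), wob[:, j])
        else:
            sd = _NOISE_ONLY[entry.activity]
            if entry.activity == "sleep":
                g = _gravity_drift(
                    m, fs, rng, base_theta_deg=65.0 + rng.uniform(-5, 5),
                    step_sd_deg=0.3 * noise_scale,
                )
                accel[i0:i1] += g - np.array([0.0, 0.0, 1.0])
                sleep_intervals.append((entry.start_s, entry.end_s))
            elif entry.activity == "nonwear":
                accel[i0:i1] = rng.normal(0.0, sd * noise_scale, (m, 3))
                accel[i0:i1, 2] += 1.0
                continue
            elif entry.activity == "unspecified_arms_sit_stand":
                # slow erratic arm movement: energy below the gait band,
                # clearly aperiodic at step frequencies
                wob = rng.normal(0.0, 1.0, (m // 150 + 2, 3))
                idx = np.linspace(0, wob.shape[0] - 1, m)
                for j in range(3):
                    accel[i0:i1, j] += sd * noise_scale * np.interp(
                        idx, np.arange(wob.shape[0]), wob[:, j])

    step_times = (
        np.sort(np.concatenate(all_steps)) if all_steps else np.zeros(0)
    )
    gt = GroundTruth(
        activity_codes=codes,
        activity_names=names,
        step_times=step_times,
        speed_ms=speed,
        sleep_intervals=sleep_intervals,
    )
    rec = RawRecording(
        time_s=time_s,
        accel=accel,
        sampling_rate_hz=fs,
        subject=subject,
        start_time_of_day_h=start_time_of_day_h,
    )
    return rec, gt


# ---------------------------------------------------------------------------
# cohort generators


def subject_usual_speed(
    sex: str,
    age_years: float,
    rng: np.random.Generator,
    between_sd: float = 0.10,
    height_cm: float | None = None,
) -> float:
    """Subject-level usual walking speed (m/s).

    Men average 0.08 m/s faster than women; speed declines 0.004 m/s per
    year past age 60 and rises 0.004 m/s per cm of body height above the
    sex-specific mean (taller people take longer strides).
    """
    base = 1.19 if sex == "male" else 1.11
    base -= 0.004 * (age_years - 60.0)
    if height_cm is not None:
        base += 0.004 * (height_cm - (177.0 if sex == "male" else 164.0))
    return float(np.clip(base + rng.normal(0.0, between_sd), 0.6, 1.8))


def _draw_subject(i: int, rng: np.random.Generator) -> SubjectMeta:
    sex = "male" if rng.random() < 0.5 else "female"
    height = rng.normal(177.0 if sex == "male" else 164.0, 7.0)
    age = rng.uniform(45.0, 79.0)
    return SubjectMeta(
        id=f"S{i:03d}", sex=sex, height_cm=float(np.clip(height, 140, 210)),
        age_years=float(age),
    )


_HAND_POSITIONS = (
    ("walk_arm_swing", 0.72),
    ("walk_pockets", 0.04),
    ("walk_texting", 0.03),
    ("walk_phone", 0.03),
    ("walk_shoulder", 0.06),
    ("walk_briefcase", 0.05),
    ("unspecified_arms_walking", 0.07),
)


def daily_schedule(
    day_start_s: float,
    usual_speed: float,
    rng: np.random.Generator,
    walking_minutes: float = 75.0,
    jitter_ms: float = 40.0,
) -> ActivitySchedule:
    """One scripted 24-h day: night sleep, daytime walking bouts and rest.

    Walking bouts use a mix of hand positions dominated by arm swing; bout
    durations are log-normal (many short walks, few long ones) and bout
    speeds scatter around the subject-day usual speed so the daily median of
    per-window speeds tracks it.  The 40 ms default step-time jitter puts
    daily step-time variability in the range seen in free-living adults.
    """
    entries: list[ScheduleEntry] = []
    wake_h = 7.0 + rng.normal(0.0, 0.3)
    bed_h = 23.0 + rng.normal(0.0, 0.3)
    entries.append(ScheduleEntry(day_start_s, wake_h * 3600.0, "sleep"))
    acts, weights = zip(*_HAND_POSITIONS)
    weights = np.asarray(weights) / sum(w for _, w in _HAND_POSITIONS)

    t = day_start_s + wake_h * 3600.0
    day_end = day_start_s + bed_h * 3600.0
    walk_budget = walking_minutes * 60.0
    while t < day_end - 120.0:
        rest = rng.uniform(300.0, 1500.0)
        rest = min(rest, day_end - t)
        act = "unspecified_arms_sit_stand" if rng.random() < 0.25 else "stationary"
        entries.append(ScheduleEntry(t, rest, act))
        t += rest
        if walk_budget <= 0 or t >= day_end - 60.0:
            continue
        dur = float(np.clip(rng.lognormal(np.log(80.0), 1.0), 8.0, 900.0))
        dur = min(dur, walk_budget, day_end - t - 30.0)
        if dur < 8.0:
            continue
        activity = str(rng.choice(acts, p=weights))
        speed = float(np.clip(usual_speed * rng.uniform(0.85, 1.15), 0.5, 2.0))
        entries.append(
            ScheduleEntry(
                t, dur, activity,
                cadence_spm=cadence_for_speed(speed),
                speed_ms=speed,
                step_time_jitter_ms=jitter_ms,
            )
        )
        walk_budget -= dur
        t += dur
    entries.append(ScheduleEntry(day_end, (24.0 - bed_h) * 3600.0, "sleep"))
    return entries


def synthesize_cohort(
    n_subjects: int,
    days: int,
    seed: int,
    cfg: PipelineConfig | None = None,
    between_sd: float = 0.10,
    within_sd: float = 0.03,
    walking_minutes: float = 75.0,
) -> list[CohortRecord]:
    """Multi-day free-living cohort with per-subject demographics.

    ``between_sd``/``within_sd`` set the subject-level and day-level
    standard deviations of usual walking speed (m/s), giving downstream
    test-retest analyses a known variance structure.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if days < 1:
        raise ValueError("days must be >= 1")
    if cfg is None:
        cfg = PipelineConfig()
    root = np.random.SeedSequence(seed)
    out = []
    for i, ss in enumerate(root.spawn(n_subjects)):
        child_seeds = ss.generate_state(2)
        rng = np.random.default_rng(int(child_seeds[0]))
        subject = _draw_subject(i, rng)
        base = subject_usual_speed(
            subject.sex, subject.age_years, rng, between_sd, subject.height_cm
        )
        schedule: ActivitySchedule = []
        for d in range(days):
            day_speed = float(np.clip(base + rng.normal(0.0, within_sd), 0.5, 2.0))
            schedule.extend(
                daily_schedule(d * 86400.0, day_speed, rng, walking_minutes)
            )
        rec, gt = synthesize_recording(
            schedule, subject, int(child_seeds[1]), cfg, start_time_of_day_h=0.0
        )
        out.append(CohortRecord(rec, gt, subject))
    return out


def development_schedule(
    usual_speed: float,
    rng: np.random.Generator,
    trial_s: float = 24.0,
    jitter_ms: float = 15.0,
) -> ActivitySchedule:
    """Laboratory-style protocol: each hand position at slow/usual/fast pace,
    plus running, unspecified arm activities and stationary blocks."""
    entries: list[ScheduleEntry] = []
    t = 0.0
    walk_classes = [
        "walk_arm_swing", "walk_pockets", "walk_texting",
        "walk_phone", "walk_shoulder", "walk_briefcase",
    ]
    for act in walk_classes:
        for pace in (0.7, 1.0, 1.3):
            passes = 2 if act == "walk_arm_swing" else 1
            for _ in range(passes):
                speed = float(np.clip(usual_speed * pace * rng.uniform(0.95, 1.05), 0.5, 2.0))
                entries.append(
                    ScheduleEntry(
                        t, trial_s, act,
                        cadence_spm=cadence_for_speed(speed),
                        speed_ms=speed,
                        step_time_jitter_ms=jitter_ms,
                    )
                )
                t += trial_s
                entries.append(ScheduleEntry(t, 8.0, "stationary"))
                t += 8.0
    for act, dur in (
        ("running", 2 * trial_s),
        ("unspecified_arms_walking", 3 * trial_s),
        ("unspecified_arms_sit_stand", 3 * trial_s),
        ("stationary", 3 * trial_s),
    ):
        if act in STEPPED:
            speed = 3.0 if act == "running" else usual_speed
            cad = 170.0 if act == "running" else cadence_for_speed(speed)
            entries.append(
                ScheduleEntry(t, dur, act, cadence_spm=cad, speed_ms=speed,
                              step_time_jitter_ms=jitter_ms)
            )
        else:
            entries.append(ScheduleEntry(t, dur, act))
        t += dur
    return entries


def synthesize_development_cohort(
    n_subjects: int,
    seed: int,
    cfg: PipelineConfig | None = None,
    trial_s: float = 24.0,
    jitter_ms: float = 15.0,
) -> list[CohortRecord]:
    """Cohort following the development protocol (for model training)."""
    if cfg is None:
        cfg = PipelineConfig()
    root = np.random.SeedSequence(seed)
    out = []
    for i, ss in enumerate(root.spawn(n_subjects)):
        child_seeds = ss.generate_state(2)
        rng = np.random.default_rng(int(child_seeds[0]))
        subject = _draw_subject(i, rng)
        speed = subject_usual_speed(
            subject.sex, subject.age_years, rng, height_cm=subject.height_cm
        )
        schedule = development_schedule(speed, rng, trial_s, jitter_ms)
        rec, gt = synthesize_recording(schedule, subject, int(child_seeds[1]), cfg)
        out.append(CohortRecord(rec, gt, subject))
    return out


# ---------------------------------------------------------------------------
# ground-truth annotation of window frames


def window_truth(
    frame: WindowFrame, gt: GroundTruth, recording: RawRecording
) -> dict[str, np.ndarray]:
    """Per-window ground truth: majority activity labels, speed, step count."""
    fs = frame.sampling_rate_hz
    w = frame.samples_per_window
    n = frame.n_windows
    stage1 = np.empty(n, dtype=object)
    stage2 = np.empty(n, dtype=object)
    speed = np.full(n, np.nan)
    steps = np.zeros(n)
    t0 = recording.time_s[0]
    for i in range(n):
        s = int(round((frame.start_times[i] - t0) * fs))
        codes = gt.activity_codes[s : s + w]
        major = np.bincount(codes).argmax()
        act = gt.activity_names[major]
        stage1[i], s2 = ACTIVITIES[act]
        stage2[i] = s2 if s2 is not None else ""
        spd = gt.speed_ms[s : s + w]
        if np.isfinite(spd).mean() >= 0.5:
            speed[i] = np.nanmean(spd)
    lo = np.searchsorted(gt.step_times, frame.start_times)
    hi = np.searchsorted(gt.step_times, frame.start_times + w / fs)
    steps = (hi - lo).astype(float)
    return {
        "stage1": stage1, "stage2": stage2,
        "speed_ms": speed, "step_count": steps,
    }


def labelled_frame(
    record: CohortRecord, cfg: PipelineConfig | None = None
) -> WindowFrame:
    """Preprocess a cohort record and attach ground-truth window labels."""
    if cfg is None:
        cfg = PipelineConfig()
    frame = make_frame(record.recording, cfg)
    truth = window_truth(frame, record.ground_truth, record.recording)
    frame.stage1 = truth["stage1"]
    frame.stage2 = truth["stage2"]
    frame.truth = truth
    return frame


# ---------------------------------------------------------------------------
# two-way random-effects biomarker matrices (test-retest structure)


def icc_theoretical(
    k: int, sigma_subject: float, sigma_day: float, sigma_error: float
) -> float:
    """Closed-form ICC(2,k) of the two-way random-effects generative model."""
    sr2, sc2, se2 = sigma_subject**2, sigma_day**2, sigma_error**2
    return sr2 / (sr2 + (sc2 + se2) / k)


def sigma_subject_for_icc(
    target: float, k: int, sigma_day: float, sigma_error: float
) -> float:
    """Subject SD giving a theoretical ICC(2,k) equal to *target*."""
    if not 0 < target < 1:
        raise ValueError("target ICC must be in (0, 1)")
    sc2, se2 = sigma_day**2, sigma_error**2
    return float(np.sqrt(target * (sc2 + se2) / (k * (1.0 - target))))


def two_way_matrix(
    n_subjects: int,
    k_days: int,
    sigma_subject: float,
    sigma_day: float,
    sigma_error: float,
    seed: int,
    mean: float = 0.0,
) -> np.ndarray:
    """Draw a subjects x days matrix from y_ij = mu + r_i + c_j + e_ij."""
    rng = np.random.default_rng(seed)
    r = rng.normal(0.0, sigma_subject, (n_subjects, 1))
    c = rng.normal(0.0, sigma_day, (1, k_days))
    e = rng.normal(0.0, sigma_error, (n_subjects, k_days))
    return mean + r + c + e


# ---------------------------------------------------------------------------
# on-disk forms


def write_recording_csv(recording: RawRecording, path: str | Path) -> None:
    """Delimited text with header time,x,y,z (seconds, g)."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "time": recording.time_s,
            "x": recording.accel[:, 0],
            "y": recording.accel[:, 1],
            "z": recording.accel[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def write_ground_truth_json(gt: GroundTruth, path: str | Path) -> None:
    """JSON sidecar: step times, sleep intervals and activity run-lengths."""
    codes = gt.activity_codes
    change = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [codes.size]))
    runs = [
        {"start_idx": int(s), "end_idx": int(e), "activity": gt.activity_names[codes[s]]}
        for s, e in zip(starts, ends)
    ]
    payload = {
        "step_times_s": gt.step_times.tolist(),
        "sleep_intervals_s": [list(iv) for iv in gt.sleep_intervals],
        "activity_runs": runs,
    }
    Path(path).write_text(json.dumps(payload))
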