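import numpy as np
import pytest

from watchwalk import simulate as sim
from watchwalk.errors import ScheduleError
from watchwalk.preprocess import SubjectMeta


@pytest.fixture(scope="module")
def subject():
    return SubjectMeta(id="T00", sex="female", height_cm=165.0, age_years=55.0)


def test_step_count_is_cadence_times_duration(cfg, subject):
    sched = [sim.ScheduleEntry(0, 60, "walk_arm_swing", cadence_spm=120,
                               speed_ms=1.2, step_time_jitter_ms=0)]
    _, gt = sim.synthesize_recording(sched, subject, seed=1, cfg=cfg)
    assert gt.step_times.size == 120
    assert np.all(np.diff(gt.step_times) > 0)


def test_step_counts_invariant_to_noise_seed(cfg, subject):
    sched = [sim.ScheduleEntry(0, 90, "walk_arm_swing", cadence_spm=105,
                               speed_ms=1.2, step_time_jitter_ms=20)]
    rec1, gt1 = sim.synthesize_recording(sched, subject, seed=1, cfg=cfg)
    rec2, gt2 = sim.synthesize_recording(sched, subject, seed=2, cfg=cfg)
    assert gt1.step_times.size == gt2.step_times.size
    assert not np.array_equal(rec1.accel, rec2.accel)


def test_bit_identical_under_same_seed(cfg, subject):
    sched = [
        sim.ScheduleEntry(0, 60, "walk_briefcase", cadence_spm=100, speed_ms=1.1),
        sim.ScheduleEntry(60, 120, "stationary"),
    ]
    rec1, gt1 = sim.synthesize_recording(sched, subject, seed=7, cfg=cfg)
    rec2, gt2 = sim.synthesize_recording(sched, subject, seed=7, cfg=cfg)
    np.testing.assert_array_equal(rec1.accel, rec2.accel)
    np.testing.assert_array_equal(gt1.step_times, gt2.step_times)


def test_overlapping_entries_rejected(cfg, subject):
    sched = [
        sim.ScheduleEntry(0, 60, "stationary"),
        sim.ScheduleEntry(30, 60, "stationary"),
    ]
    with pytest.raises(ScheduleError, match="overlap"):
        sim.synthesize_recording(sched, subject, seed=1, cfg=cfg)


def test_walking_entry_requires_cadence_or_speed():
    with pytest.raises(ScheduleError):
        sim.ScheduleEntry(0, 60, "walk_arm_swing")
    with pytest.raises(ScheduleError):
        sim.ScheduleEntry(0, 60, "stationary", cadence_spm=100)


def test_scheduled_cadence_recoverable_by_fourier(cfg, subject):
    for cadence in (80.0, 120.0):
        sched = [sim.ScheduleEntry(0, 120, "walk_arm_swing", cadence_spm=cadence,
                                   speed_ms=1.2, step_time_jitter_ms=0)]
        rec, _ = sim.synthesize_recording(sched, subject, seed=3, cfg=cfg)
        from watchwalk.preprocess import euclidean_norm

        x = euclidean_norm(rec)
        x = x - x.mean()
        spec = np.abs(np.fft.rfft(x))
        freqs = np.fft.rfftfreq(x.size, 1 / cfg.sampling_rate_hz)
        band = (freqs > 0.6) & (freqs < 3.5)
        f_dom = freqs[band][np.argmax(spec[band])]
        assert abs(f_dom * 60.0 - cadence) <= 2.0


def test_sleep_entry_orientation_stable(cfg, subject):
    sched = [sim.ScheduleEntry(0, 8 * 3600, "sleep")]
    rec, gt = sim.synthesize_recording(sched, subject, seed=5, cfg=cfg)
    labels = gt.sample_activity()
    assert set(labels.tolist()) == {"sleep"}
    assert gt.sleep_intervals == [(0.0, 8 * 3600.0)]
    # elevation angle of 5-s epoch medians moves < 5 degrees between epochs
    per = int(5 * cfg.sampling_rate_hz)
    n_ep = rec.n_samples // per
    med = np.median(rec.accel[: n_ep * per].reshape(n_ep, per, 3), axis=1)
    ang = np.degrees(np.arctan2(med[:, 2], np.hypot(med[:, 0], med[:, 1])))
    assert np.max(np.abs(np.diff(ang))) < 5.0


def test_cohort_shapes_and_demographics(cfg):
    records = sim.synthesize_cohort(3, days=1, seed=2, cfg=cfg,
                                    walking_minutes=10.0)
    assert len(records) == 3
    for rec in records:
        assert rec.recording.duration_s == pytest.approx(86400.0, abs=1.0)
        assert rec.subject.sex in ("female", "male")
        assert 45 <= rec.subject.age_years < 80
    with pytest.raises(ValueError):
        sim.synthesize_cohort(2, days=0, seed=1, cfg=cfg)


def test_two_way_matrix_matches_closed_form_icc():
    # degenerate: no day or error variance -> days identical per subject
    m = sim.two_way_matrix(5, 4, sigma_subject=1.0, sigma_day=0.0,
                           sigma_error=0.0, seed=0)
    assert np.allclose(m, m[:, :1])
    assert sim.icc_theoretical(4, 1.0, 0.0, 0.0) == 1.0
    # solving for the subject SD reproduces the target exactly
    for target in (0.5, 0.8, 0.95):
        sr = sim.sigma_subject_for_icc(target, 7, 0.2, 1.0)
        assert sim.icc_theoretical(7, sr, 0.2, 1.0) == pytest.approx(target)


def test_development_cohort_covers_all_classes(cfg, dev_cohort):
    _, frames = dev_cohort
    seen = set()
    for f in frames:
        seen.update(f.stage1.tolist())
    assert seen == {
        "walk_arm_swing", "other_complex_walking", "running", "stationary",
        "unspecified_arms_sit_stand", "unspecified_arms_walking",
    }
    s2 = set()
    for f in frames:
        s2.update(x for x in f.stage2.tolist() if x)
    assert len(s2) == 5
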