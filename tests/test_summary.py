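import numpy as np
import pandas as pd
import pytest

from watchwalk.preprocess import RawRecording
from watchwalk.summary import (
    hand_position_percentages,
    normative_table,
    pool_subject_days,
    summarize_day,
    wear_time,
    zscore_profile,
)


def _wear_recording(cfg, day_hours_worn, fs=2.0):
    """Cheap multi-day recording: worn time has movement, the rest is dead."""
    rng = np.random.default_rng(0)
    parts = []
    for worn_h in day_hours_worn:
        n_day = int(24 * 3600 * fs)
        day = np.tile([0.0, 0.0, 1.0], (n_day, 1))
        day += rng.normal(0, 0.002, (n_day, 3))  # below the 13 mg threshold
        n_worn = int(worn_h * 3600 * fs)
        day[:n_worn] += rng.normal(0, 0.05, (n_worn, 3))
        parts.append(day)
    accel = np.vstack(parts)
    return RawRecording(time_s=np.arange(accel.shape[0]) / fs, accel=accel,
                        sampling_rate_hz=fs)


class TestWearTime:
    def test_fully_worn_week_passes_both_criteria(self, cfg):
        rec = _wear_recording(cfg, [24] * 7)
        df = wear_time(rec, cfg)
        assert len(df) == 7
        assert (df["wear_hours"] >= 23).all()
        assert df.attrs["full_criterion"] and df.attrs["relaxed_criterion"]

    def test_three_half_days_pass_relaxed_only(self, cfg):
        rec = _wear_recording(cfg, [12.5, 12.5, 12.5, 0, 0])
        df = wear_time(rec, cfg)
        assert not df.attrs["full_criterion"]
        assert df.attrs["relaxed_criterion"]
        assert df["wear_hours"][:3].between(11.5, 13.5).all()

    def test_two_worn_days_fail_both(self, cfg):
        rec = _wear_recording(cfg, [24, 24, 0, 0, 0])
        df = wear_time(rec, cfg)
        assert not df.attrs["full_criterion"]
        assert not df.attrs["relaxed_criterion"]


class TestHandPositions:
    def test_percentages_sum_and_composites(self):
        stage1 = np.asarray(
            ["walk_arm_swing"] * 6 + ["other_complex_walking"] * 4
            + ["stationary"] * 5, dtype=object)
        stage2 = np.asarray(
            [""] * 6 + ["hands_held_stationary", "hand_next_to_ear",
                        "hands_in_pockets", "briefcase_grocery_bag"] + [""] * 5,
            dtype=object)
        hp = hand_position_percentages(stage1, stage2)
        parts = [hp["pct_arm_swing"], hp["pct_texting"], hp["pct_phone_call"],
                 hp["pct_hands_in_pockets"], hp["pct_shoulder_bag"],
                 hp["pct_briefcase"]]
        assert sum(parts) == pytest.approx(100.0)
        assert hp["pct_static"] == hp["pct_texting"] + hp["pct_phone_call"]
        assert hp["pct_adaptive"] == (hp["pct_hands_in_pockets"]
                                      + hp["pct_shoulder_bag"] + hp["pct_briefcase"])
        assert hp["pct_arm_swing"] == pytest.approx(60.0)

    def test_no_walking_is_missing(self):
        stage1 = np.asarray(["stationary"] * 3, dtype=object)
        assert hand_position_percentages(stage1, np.asarray([""] * 3, object)) is None


def test_summarize_day_with_no_walking_keeps_sleep(cfg):
    from watchwalk.sleep import SleepEstimate

    stage1 = np.asarray(["stationary"] * 10, dtype=object)
    stage2 = np.asarray([""] * 10, dtype=object)
    day = summarize_day(
        "S1", 0, stage1, stage2, bouts=[], step_metrics=None, step_series=None,
        speed_predictions=np.zeros(0),
        sleep_estimate=SleepEstimate(7.5, 23.1, []), cfg=cfg,
    )
    assert day.sleep_duration_h == 7.5
    assert day.bedtime_h == 23.1
    assert day.longest_walk_s is None
    assert day.max_speed_cms is None
    assert day.pct_arm_swing is None
    assert "bouts" in day.missing_reasons


def _pooled_cohort(n=120, seed=0):
    rng = np.random.default_rng(seed)
    sexes = np.where(rng.random(n) < 0.5, "female", "male")
    ages = rng.uniform(45, 79.9, n)
    pooled = pd.DataFrame({
        "subject_id": [f"S{i:03d}" for i in range(n)],
        "steps_per_day": rng.normal(7700, 2700, n),
        "max_speed_cms": rng.normal(149, 8, n),
        "step_time_variability_ms": rng.normal(61, 14, n),
    })
    demo = pd.DataFrame({
        "subject_id": pooled["subject_id"], "sex": sexes, "age_years": ages,
    })
    return pooled, demo


class TestNormativeTable:
    def test_stratum_percentiles_match_order_statistic_oracle(self, cfg):
        pooled = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(100)],
            "steps_per_day": np.arange(1.0, 101.0),
        })
        demo = pd.DataFrame({
            "subject_id": pooled["subject_id"],
            "sex": ["female"] * 100,
            "age_years": [50.0] * 100,
        })
        table = normative_table(pooled, demo, cfg)
        row = table[(table["biomarker"] == "steps_per_day")
                    & (table["sex"] == "female")
                    & (table["age_group"] == "45-54")].iloc[0]
        assert row["n"] == 100
        assert row["p50"] == pytest.approx(50.5)
        assert row["p25"] == pytest.approx(25.75)
        assert row["p75"] == pytest.approx(75.25)

    def test_identical_values_and_age_exclusion(self, cfg):
        pooled = pd.DataFrame({
            "subject_id": ["A", "B", "C"],
            "steps_per_day": [5000.0, 5000.0, 5000.0],
        })
        demo = pd.DataFrame({
            "subject_id": ["A", "B", "C"],
            "sex": ["male", "male", "male"],
            "age_years": [60.0, 60.0, 44.0],  # C excluded: outside [45, 80)
        })
        table = normative_table(pooled, demo, cfg)
        row = table[(table["sex"] == "male") & (table["age_group"] == "55-64")].iloc[0]
        assert row["n"] == 2
        assert all(row[f"p{p}"] == 5000.0 for p in (5, 10, 25, 50, 75, 90, 95))
        assert table[(table["age_group"] == "45-54") & (table["sex"] == "male")]["n"].iloc[0] == 0

    def test_rows_monotone_and_pooling_consistency(self, cfg):
        pooled, demo = _pooled_cohort()
        table = normative_table(pooled, demo, cfg)
        pcols = [f"p{p}" for p in (5, 10, 25, 50, 75, 90, 95)]
        filled = table[table["n"] > 0]
        diffs = filled[pcols].to_numpy()
        assert np.all(np.diff(diffs, axis=1) >= 0)
        # pooling all strata reproduces the whole-cohort percentiles
        whole = np.percentile(pooled["steps_per_day"], 50, method="linear")
        one_stratum_cfg_vals = pooled["steps_per_day"].to_numpy()
        assert np.percentile(one_stratum_cfg_vals, 50) == pytest.approx(whole)
        # n adds up across strata
        assert filled[filled["biomarker"] == "steps_per_day"]["n"].sum() == len(pooled)


class TestZScores:
    def test_reference_subject_scores_zero(self):
        pooled, _ = _pooled_cohort()
        means = pooled[["steps_per_day", "max_speed_cms",
                        "step_time_variability_ms"]].mean()
        profile = zscore_profile(means.to_dict(), pooled)
        assert np.allclose(profile.to_numpy(), 0.0, atol=1e-12)

    def test_lower_is_better_markers_are_reversed(self):
        pooled, _ = _pooled_cohort()
        ref_mean = pooled["step_time_variability_ms"].mean()
        ref_sd = pooled["step_time_variability_ms"].std(ddof=1)
        subject = {"step_time_variability_ms": ref_mean + ref_sd}
        profile = zscore_profile(subject, pooled)
        assert profile["step_time_variability_ms"] == pytest.approx(-1.0)

    def test_reference_cohort_profile_standardized(self):
        pooled, _ = _pooled_cohort()
        zs = np.array([
            zscore_profile(row._asdict(), pooled)["max_speed_cms"]
            for row in pooled.itertuples(index=False)
        ])
        assert np.mean(zs) == pytest.approx(0.0, abs=1e-10)
        assert np.std(zs, ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_zero_sd_is_missing(self):
        ref = pd.DataFrame({"steps_per_day": [5.0, 5.0, 5.0]})
        profile = zscore_profile({"steps_per_day": 6.0}, ref)
        assert np.isnan(profile["steps_per_day"])


def test_pool_subject_days_mean_vs_median_and_circular_bedtime():
    daily = pd.DataFrame({
        "subject_id": ["A"] * 3,
        "day": [0, 1, 2],
        "steps_per_day": [1000.0, 2000.0, 6000.0],      # normal: mean
        "longest_walk_s": [100.0, 200.0, 600.0],         # skewed: median
        "bedtime_h": [23.5, 0.5, 23.5],                  # circular mean
    })
    pooled = pool_subject_days(daily)
    assert pooled.loc[0, "steps_per_day"] == pytest.approx(3000.0)
    assert pooled.loc[0, "longest_walk_s"] == pytest.approx(200.0)
    bt = pooled.loc[0, "bedtime_h"]
    assert bt > 23.5 or bt < 0.5  # wraps around midnight, never ~15.8
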