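import numpy as np
import pandas as pd
import pytest

from watchwalk import simulate as sim
from watchwalk.errors import EstimationError
from watchwalk.validation import icc_2k, mape, stratified_contrast


def _anova_oracle(m):
    """Brute-force two-way ANOVA mean squares by explicit sums of squares."""
    n, k = m.shape
    grand = m.mean()
    ss_rows = sum(k * (m[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (m[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((m[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (msc - mse) / n)


class TestIcc:
    def test_identical_days_per_subject(self):
        m = np.tile(np.array([[3.0], [7.0], [5.0]]), (1, 4))
        res = icc_2k(m)
        assert res.icc == 1.0
        assert res.ci95[0] <= 1.0 <= res.ci95[1]

    def test_matches_brute_force_anova_oracle(self):
        m = np.array([[9.0, 8], [6, 5], [4, 3], [7, 6]])
        res = icc_2k(m)
        assert res.icc == pytest.approx(_anova_oracle(m), abs=1e-10)
        rng = np.random.default_rng(1)
        m2 = rng.normal(5, 2, (8, 5)) + rng.normal(0, 1.5, (8, 1))
        assert icc_2k(m2).icc == pytest.approx(_anova_oracle(m2), abs=1e-10)

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        m = rng.normal(5, 2, (6, 4)) + rng.normal(0, 1, (6, 1))
        res = icc_2k(m)
        df = pd.DataFrame({
            "s": np.repeat(range(6), 4), "d": list(range(4)) * 6, "v": m.ravel(),
        })
        table = pg.intraclass_corr(df, targets="s", raters="d", ratings="v")
        row = table[table["Type"] == "ICC(A,k)"]
        if row.empty:
            row = table[table["Type"] == "ICC2k"]
        ref = row.iloc[0]
        assert res.icc == pytest.approx(float(ref["ICC"]), abs=1e-9)
        lo, hi = ref["CI95"] if "CI95" in table.columns else ref["CI95%"]
        assert res.ci95[0] == pytest.approx(lo, abs=0.01)
        assert res.ci95[1] == pytest.approx(hi, abs=0.01)

    def test_null_cohort_near_zero(self):
        m = sim.two_way_matrix(200, 7, 0.0, 0.0, 1.0, seed=5)
        assert abs(icc_2k(m).icc) <= 0.15

    def test_generative_targets_recovered(self):
        for target in (0.5, 0.8, 0.95):
            sr = sim.sigma_subject_for_icc(target, 7, 0.2, 1.0)
            ests = [
                icc_2k(sim.two_way_matrix(100, 7, sr, 0.2, 1.0, seed=s)).icc
                for s in range(20)
            ]
            assert np.mean(ests) == pytest.approx(target, abs=0.05)

    def test_shift_and_scale_invariance(self):
        m = sim.two_way_matrix(30, 5, 1.0, 0.3, 0.8, seed=2)
        base = icc_2k(m).icc
        assert icc_2k(m + 100.0).icc == pytest.approx(base, abs=1e-10)
        assert icc_2k(m * 3.7).icc == pytest.approx(base, abs=1e-10)

    def test_incomplete_rows_dropped_and_errors(self):
        m = np.array([[1.0, 2], [np.nan, 3], [4, 5], [6, 7]])
        res = icc_2k(m)
        assert res.n_subjects == 3
        with pytest.raises(EstimationError):
            icc_2k(np.array([[1.0, 2], [np.nan, 3]]))
        with pytest.raises(EstimationError):
            icc_2k(np.array([[1.0], [2.0]]))


class TestMape:
    def test_examples(self):
        truth = np.array([1.0, 2.0, 3.0])
        assert mape(truth, truth) == (0.0, 0.0)
        mean, sd = mape(1.1 * truth, truth)
        assert mean == pytest.approx(10.0)
        assert sd == pytest.approx(0.0, abs=1e-9)
        mean, _ = mape(np.array([1.0, 2.2, 2.7]), truth)
        assert mean == pytest.approx(np.mean([0.0, 10.0, 10.0]))

    def test_zero_truth_names_index(self):
        with pytest.raises(ValueError, match="index 1"):
            mape(np.array([1.0, 1.0]), np.array([1.0, 0.0]))


class TestStratifiedContrast:
    def test_identical_groups(self):
        v = np.concatenate([np.arange(10.0), np.arange(10.0)])
        g = np.array(["a"] * 10 + ["b"] * 10)
        df = stratified_contrast(v, g)
        assert df.loc[0, "mean"] == df.loc[1, "mean"]
        assert df.loc[0, "sd"] == df.loc[1, "sd"]

    def test_generator_sex_offset_recovered(self):
        rng = np.random.default_rng(12)
        speeds, sexes = [], []
        for i in range(400):
            sex = "male" if i % 2 else "female"
            speeds.append(100 * sim.subject_usual_speed(sex, 62.0, rng,
                                                        between_sd=0.08))
            sexes.append(sex)
        df = stratified_contrast(np.asarray(speeds), np.asarray(sexes))
        means = df.set_index("group")["mean"]
        assert means["male"] - means["female"] == pytest.approx(8.0, abs=1.0)
        assert df.attrs["p_value"] < 0.001

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            stratified_contrast(np.arange(5.0), np.array(["a"] * 5))
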