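import numpy as np
import pandas as pd
import pytest

import torsomorph as tm
from torsomorph.errors import (
    ConfigurationError,
    DegenerateCohortError,
    SingularDesignError,
)
from torsomorph.stats import f_from_r_squared, r_squared_from_beta


def anthro_frame(**overrides):
    base = {
        "stature_m": [1.70, 1.80, 1.90],
        "mass_kg": [70.0, 80.0, 90.0],
        "waist_girth_m": [0.80, 0.86, 0.95],
        "hip_girth_m": [0.95, 1.00, 1.05],
        "skinfold_iliac_crest_mm": [15.0, 17.0, 20.0],
        "skinfold_supraspinale_mm": [10.0, 11.0, 13.0],
        "skinfold_abdominal_mm": [20.0, 23.0, 26.0],
    }
    base.update(overrides)
    return pd.DataFrame(base)


class TestDeriveIndices:
    def test_bmi_hand_example(self):
        df = anthro_frame(mass_kg=[80.0, 80.0, 80.0], stature_m=[2.0, 2.0, 2.0])
        out = tm.derive_indices(df)
        np.testing.assert_allclose(out["bmi"], 20.0)

    def test_whr_equal_girths(self):
        df = anthro_frame(waist_girth_m=[1.0, 1.0, 1.0], hip_girth_m=[1.0, 1.0, 1.0])
        assert (tm.derive_indices(df)["whr"] == 1.0).all()

    def test_wht5r_hand_example(self):
        df = anthro_frame(waist_girth_m=[0.8606] * 3, stature_m=[1.798] * 3)
        out = tm.derive_indices(df)
        assert out["wht5r"].iloc[0] == pytest.approx(0.8606 / np.sqrt(1.798), abs=1e-12)
        assert out["wht5r"].iloc[0] == pytest.approx(0.6418, abs=5e-4)

    def test_sum_skinfolds_and_missing_propagation(self):
        df = anthro_frame()
        df.loc[1, "skinfold_abdominal_mm"] = np.nan
        out = tm.derive_indices(df)
        assert out["sum_skinfolds_mm"].iloc[0] == pytest.approx(45.0)
        assert np.isnan(out["sum_skinfolds_mm"].iloc[1])

    def test_nonpositive_inputs_rejected(self):
        df = anthro_frame(mass_kg=[70.0, -1.0, 90.0])
        with pytest.raises(Exception, match="mass_kg"):
            tm.derive_indices(df)


class TestZScore:
    def test_simple_column(self):
        out = tm.zscore_table(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(out["x"], [-1, 0, 1])

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        out = tm.zscore_table(pd.DataFrame({"x": rng.uniform(0, 10, 100)}))
        assert out["x"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["x"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x": rng.normal(5, 2, 50)})
        once = tm.zscore_table(df)
        twice = tm.zscore_table(once)
        np.testing.assert_allclose(twice["x"], once["x"], atol=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateCohortError):
            tm.zscore_table(pd.DataFrame({"x": [2.0, 2.0, 2.0]}))


class TestPearsonMatrix:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        corr = tm.pearson_matrix(pd.DataFrame({"x": x, "y": 2 * x + 1}))
        assert corr.r.loc["x", "y"] == pytest.approx(1.0)
        assert corr.p.loc["x", "y"] < 1e-10

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(5000)
        y = rng.permutation(x)
        corr = tm.pearson_matrix(pd.DataFrame({"x": x, "y": y}))
        assert abs(corr.r.loc["x", "y"]) < 0.05

    def test_symmetry_diagonal_and_bounds(self, descriptor_cohort_43):
        _, _, anthro, _ = descriptor_cohort_43
        derived = tm.derive_indices(anthro)
        corr = tm.pearson_matrix(derived, columns=["waist_girth_m", "bmi", "whr",
                                                   "sum_skinfolds_mm"])
        R = corr.r.to_numpy()
        np.testing.assert_allclose(R, R.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(R), 1.0)
        assert np.nanmax(np.abs(R)) <= 1.0 + 1e-12

    def test_generative_waist_ssf_correlation_recovered(self):
        """The generator links SSF to waist with a known coefficient; at
        n=2000 the sample correlation lands on the generative target."""
        spec = tm.CohortSpec(n_participants=2000, seed=3,
                             missing_skinfold_fraction=0.0)
        rng = np.random.default_rng(4)
        amps = np.vstack([tm.synthetic.draw_amplitudes(spec, rng)
                          for _ in range(2000)])
        table, _ = tm.synthetic.generate_anthro(spec, rng, amps)
        derived = tm.derive_indices(table)
        corr = tm.pearson_matrix(derived, columns=["waist_girth_m", "sum_skinfolds_mm"])
        ssf = spec.ssf_model
        target = ssf.waist_coeff / np.sqrt(
            ssf.waist_coeff ** 2 + sum(c ** 2 for c in ssf.mode_coeffs)
            + ssf.noise_sd ** 2)
        assert corr.r.loc["waist_girth_m", "sum_skinfolds_mm"] == pytest.approx(
            target, abs=0.04)

    def test_pairwise_complete_with_missing(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, np.nan], "y": [2.0, 4, 6, 8, 10]})
        corr = tm.pearson_matrix(df)
        assert corr.n.loc["x", "y"] == 4
        assert corr.r.loc["x", "y"] == pytest.approx(1.0)


def zscored(df):
    return tm.zscore_table(df)


class TestFitRegression:
    def test_single_predictor_closed_form(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(200)
        y = 0.6 * x + 0.8 * rng.standard_normal(200)
        z = zscored(pd.DataFrame({"y": y, "x": x}))
        res = tm.fit_regression(z, "y", ["x"])
        r = np.corrcoef(x, y)[0, 1]
        assert res.standardized_betas["x"] == pytest.approx(r, abs=1e-12)
        assert res.r_squared == pytest.approx(r ** 2, abs=1e-12)
        assert res.vif["x"] == 1.0 and res.tolerance["x"] == 1.0

    def test_durbin_watson_hand_example(self):
        # x chosen so the residuals of y = x + e are exactly (1,-1,1,-1)
        x = np.array([0.0, 1.0, 1.0, 0.0])
        e = np.array([1.0, -1.0, 1.0, -1.0])
        df = pd.DataFrame({"y": 2.0 * x + e, "x": x})
        res = tm.fit_regression(df, "y", ["x"])
        assert res.durbin_watson == pytest.approx(3.0, abs=1e-9)

    def test_orthogonal_predictors_unit_vif(self):
        rng = np.random.default_rng(6)
        n = 128
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        y = x1 + 0.5 * x2 + rng.standard_normal(n)
        z = zscored(pd.DataFrame({"y": y, "x1": x1, "x2": x2}))
        res = tm.fit_regression(z, "y", ["x1", "x2"])
        assert res.vif["x1"] == pytest.approx(1.0, abs=1e-9)
        assert res.vif["x2"] == pytest.approx(1.0, abs=1e-9)

    def test_duplicate_predictor_singular(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(30)
        df = pd.DataFrame({"y": rng.standard_normal(30), "a": x, "b": x})
        with pytest.raises(SingularDesignError):
            tm.fit_regression(df, "y", ["a", "b"])

    def test_ols_matches_normal_equations(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((40, 3))
        y = X @ [1.0, -2.0, 0.5] + rng.standard_normal(40)
        df = pd.DataFrame(np.column_stack([y, X]), columns=["y", "a", "b", "c"])
        res = tm.fit_regression(df, "y", ["a", "b", "c"])
        A = np.column_stack([np.ones(40), X])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert res.intercept == pytest.approx(beta[0], abs=1e-9)
        for j, name in enumerate(["a", "b", "c"]):
            assert res.coefficients[name] == pytest.approx(beta[j + 1], abs=1e-9)

    def test_vif_matches_definitional_regressions(self):
        rng = np.random.default_rng(9)
        base = rng.standard_normal(60)
        X = np.column_stack([base + 0.5 * rng.standard_normal(60),
                             base + 0.5 * rng.standard_normal(60),
                             rng.standard_normal(60)])
        y = X.sum(axis=1) + rng.standard_normal(60)
        df = pd.DataFrame(np.column_stack([y, X]), columns=["y", "a", "b", "c"])
        res = tm.fit_regression(df, "y", ["a", "b", "c"])
        for j, name in enumerate(["a", "b", "c"]):
            others = np.delete(X, j, axis=1)
            A = np.column_stack([np.ones(60), others])
            fitted = A @ np.linalg.lstsq(A, X[:, j], rcond=None)[0]
            ss_res = np.sum((X[:, j] - fitted) ** 2)
            ss_tot = np.sum((X[:, j] - X[:, j].mean()) ** 2)
            r2_j = 1 - ss_res / ss_tot
            assert res.vif[name] == pytest.approx(1.0 / (1.0 - r2_j), abs=1e-9)
            assert res.tolerance[name] * res.vif[name] == pytest.approx(1.0, abs=1e-12)
            assert res.vif[name] >= 1.0

    def test_f_r2_identity_and_nesting(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((50, 3))
        y = X[:, 0] + rng.standard_normal(50)
        df = pd.DataFrame(np.column_stack([y, X]), columns=["y", "a", "b", "c"])
        small = tm.fit_regression(df, "y", ["a"])
        big = tm.fit_regression(df, "y", ["a", "b", "c"])
        for res in (small, big):
            assert res.f_statistic == pytest.approx(
                f_from_r_squared(res.r_squared, *res.df), rel=1e-9)
            assert 0.0 <= res.durbin_watson <= 4.0
        assert big.r_squared >= small.r_squared  # nested models


class TestPrintedWorkedExamples:
    """Closed-form identities instantiated with published single-predictor
    regression values for the waist-hip ratio model."""

    def test_r_squared_from_standardized_beta(self):
        assert r_squared_from_beta(0.553) == pytest.approx(0.306, abs=5e-4)

    def test_f_from_r_squared_and_df(self):
        assert f_from_r_squared(0.306, 1, 35) == pytest.approx(15.43, abs=0.01)


class TestStepwise:
    def test_signal_variable_selected_noise_excluded(self):
        rng = np.random.default_rng(11)
        x1 = rng.standard_normal(200)
        x2 = rng.standard_normal(200)
        y = x1 + 0.3 * rng.standard_normal(200)
        df = zscored(pd.DataFrame({"y": y, "x1": x1, "x2": x2}))
        res = tm.stepwise_select(df, "y", ["x1", "x2"])
        assert res.predictors == ["x1"]
        assert res.selection_trace[0]["variable"] == "x1"

    def test_pure_noise_pool_selects_empty(self):
        rng = np.random.default_rng(12)
        cols = {f"x{i}": rng.standard_normal(200) for i in range(11)}
        df = pd.DataFrame({"y": rng.standard_normal(200), **cols})
        res = tm.stepwise_select(df, "y", list(cols))
        assert res.predictors == []
        assert res.r_squared == 0.0

    def test_exact_linear_combination_fully_recovered(self):
        rng = np.random.default_rng(13)
        x1, x2 = rng.standard_normal((2, 50))
        y = 2.0 * x1 - x2
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        res = tm.stepwise_select(df, "y", ["x1", "x2"])
        assert set(res.predictors) == {"x1", "x2"}
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_invalid_thresholds_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2, 3], "x": [1.0, 2, 4]})
        with pytest.raises(ConfigurationError):
            tm.stepwise_select(df, "y", ["x"], p_enter=0.10, p_remove=0.05)

    def test_classic_entry_rule_available(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal(100)
        y = 0.4 * x + rng.standard_normal(100)
        df = pd.DataFrame({"y": y, "x": x})
        res = tm.stepwise_select(df, "y", ["x"], entry_correction="none")
        assert res.predictors == ["x"]


@pytest.fixture(scope="module")
def ztable(descriptor_cohort_43):
    _, matrix, anthro, _ = descriptor_cohort_43
    model, scores = tm.fit_shape_pca(matrix)
    n_pc = min(11, scores.shape[1])
    merged = tm.derive_indices(anthro).merge(
        scores.iloc[:, :n_pc], left_on="participant_id", right_index=True)
    cols = ["sum_skinfolds_mm", "stature_m", "mass_kg", "waist_girth_m",
            "hip_girth_m", "bmi", "whr", "wht5r"] + list(scores.columns[:n_pc])
    return tm.zscore_table(merged, columns=cols), n_pc


class TestModelFamilies:

    def test_family_count_is_ten(self, ztable):
        z, n_pc = ztable
        models = tm.run_model_families(z, n_shape_candidates=n_pc)
        assert len(models) == 10
        assert set(models) == {
            "size_bmi", "size_whr", "size_waist", "size_wht5r", "size_all",
            "shape_stepwise", "combined_bmi", "combined_whr", "combined_waist",
            "combined_wht5r"}

    def test_combined_never_below_index_only(self, ztable):
        z, n_pc = ztable
        models = tm.run_model_families(z, n_shape_candidates=n_pc)
        for name in ("bmi", "whr", "waist", "wht5r"):
            assert models[f"combined_{name}"].r_squared >= (
                models[f"size_{name}"].r_squared - 1e-12)

    def test_single_predictor_r2_equals_beta_squared(self, ztable):
        z, n_pc = ztable
        models = tm.run_model_families(z, n_shape_candidates=n_pc)
        for name in ("size_bmi", "size_whr", "size_waist", "size_wht5r"):
            res = models[name]
            (beta,) = res.standardized_betas.values()
            assert res.r_squared == pytest.approx(beta ** 2, abs=1e-12)

    def test_deterministic_output(self, ztable):
        z, n_pc = ztable
        m1 = tm.run_model_families(z, n_shape_candidates=n_pc)
        m2 = tm.run_model_families(z, n_shape_candidates=n_pc)
        for k in m1:
            assert m1[k].to_dict() == m2[k].to_dict()

    def test_listwise_deletion_reports_n_used(self, ztable):
        z, n_pc = ztable
        models = tm.run_model_families(z, n_shape_candidates=n_pc)
        # 6 of 43 participants lack skinfolds in the default cohort
        assert models["size_bmi"].n_used == 37
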