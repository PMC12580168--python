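import numpy as np
import pandas as pd
import pytest

from pvpassport import (
    DEFAULT_WEIGHTS,
    PVModel,
    Sex,
    estimate_pv,
    sensitivity_analysis,
    train_pv_model,
    validate_pv_model,
    weighting_index,
)
from pvpassport.pvmodel import DEFAULT_FEATURES, pv_hb_regression

from conftest import make_linear_frame


class _ConstantPipeline:
    """Stub regressor with no feature dependence."""

    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full(len(X), self.value)


class TestTraining:
    def test_exact_linear_function_recovered(self, linear_frame, linear_model):
        """A realizable linear target is fitted to numerical precision."""
        held = make_linear_frame(n=40, seed=99)
        pred = linear_model.predict_frame(held)
        np.testing.assert_allclose(
            pred, held["pv_measured"].to_numpy(), atol=1.0
        )

    def test_weight_free_identical_when_weight_uninformative(self, linear_frame):
        """Constant body weight carries no signal: dropping it changes nothing."""
        full = train_pv_model(linear_frame, regressor_kind="linear", seed=0)
        free = train_pv_model(
            linear_frame, regressor_kind="linear", weight_free=True, seed=0
        )
        held = make_linear_frame(n=40, seed=99)
        np.testing.assert_allclose(
            full.predict_frame(held), free.predict_frame(held), atol=1e-6
        )
        assert "weight" not in free.feature_list

    def test_too_few_samples_refused(self, linear_frame):
        with pytest.raises(ValueError, match="at least 30"):
            train_pv_model(linear_frame.head(10))

    def test_missing_pv_labels_refused(self, linear_frame):
        with pytest.raises(KeyError, match="pv_measured"):
            train_pv_model(linear_frame.drop(columns=["pv_measured"]))

    def test_unknown_regressor_kind(self, linear_frame):
        with pytest.raises(ValueError, match="regressor_kind"):
            train_pv_model(linear_frame, regressor_kind="mlp")

    def test_training_reproducible_under_seed(self, linear_frame):
        a = train_pv_model(linear_frame, regressor_kind="tree_ensemble", seed=3)
        b = train_pv_model(linear_frame, regressor_kind="tree_ensemble", seed=3)
        held = make_linear_frame(n=20, seed=5)
        np.testing.assert_array_equal(
            a.predict_frame(held), b.predict_frame(held)
        )


class TestEstimate:
    def test_deterministic_for_duplicate_sample(self, linear_model, linear_frame):
        row = linear_frame.iloc[0]
        assert estimate_pv(linear_model, row).pv == estimate_pv(linear_model, row).pv

    def test_missing_feature_named(self, linear_model, linear_frame):
        with pytest.raises(KeyError, match="hct"):
            linear_model.predict_frame(linear_frame.drop(columns=["hct"]))

    def test_floor_clamp_warns(self, linear_frame):
        model = PVModel(
            _ConstantPipeline(-50.0), DEFAULT_FEATURES, "linear", False
        )
        with pytest.warns(UserWarning, match="clamped"):
            pv = model.predict_frame(linear_frame.head(3))
        assert (pv == 100.0).all()

    def test_artifact_roundtrip(self, linear_model, linear_frame, tmp_path):
        path = tmp_path / "model.joblib"
        linear_model.save(path)
        loaded = PVModel.load(path)
        np.testing.assert_array_equal(
            linear_model.predict_frame(linear_frame),
            loaded.predict_frame(linear_frame),
        )


class TestSensitivity:
    def test_closed_form_for_linear_regressor(self, linear_model, linear_frame):
        """cell(hb, p%) = β · (p/100) · mean(hb) for a slope-β linear fit."""
        grid = sensitivity_analysis(
            linear_model, linear_frame, levels=[0.1], markers=["hb"]
        )
        expected = 5.0 * 0.001 * linear_frame["hb"].mean()
        assert grid.loc[0.1, "hb"] == pytest.approx(expected, rel=1e-6)

    def test_linear_scaling_across_levels(self, linear_model, linear_frame):
        grid = sensitivity_analysis(
            linear_model, linear_frame, levels=[0.05, 0.2], markers=["hb"]
        )
        ratio = grid.loc[0.2, "hb"] / grid.loc[0.05, "hb"]
        assert ratio == pytest.approx(4.0, rel=1e-6)

    def test_zero_level_exactly_zero(self, linear_model, linear_frame):
        grid = sensitivity_analysis(
            linear_model, linear_frame, levels=[0.0], markers=["hb", "hct"]
        )
        assert (grid.to_numpy() == 0.0).all()

    def test_constant_model_all_zero(self, linear_frame):
        model = PVModel(
            _ConstantPipeline(3500.0), DEFAULT_FEATURES, "linear", False
        )
        grid = sensitivity_analysis(model, linear_frame)
        assert np.allclose(grid.to_numpy(dtype=float), 0.0)

    def test_unknown_marker_rejected(self, linear_model, linear_frame):
        with pytest.raises(ValueError, match="unknown CBC marker"):
            sensitivity_analysis(
                linear_model, linear_frame, markers=["albumin"]
            )

    def test_only_named_marker_perturbed(self, linear_model, linear_frame):
        """[Hb] drives this fit, so perturbing any other marker moves nothing."""
        grid = sensitivity_analysis(
            linear_model, linear_frame, levels=[0.2], markers=["hct", "mcv"]
        )
        assert np.allclose(grid.to_numpy(dtype=float), 0.0, atol=1e-9)


class TestValidation:
    def test_identity(self):
        report = validate_pv_model([3000, 3200, 3400], [3000, 3200, 3400])
        assert report.spearman_r == pytest.approx(1.0)
        assert report.bland_altman.bias == pytest.approx(0.0)

    def test_constant_offset(self):
        est = np.array([3100.0, 3300.0, 3500.0])
        report = validate_pv_model(est, est - 100.0)
        assert report.spearman_r == pytest.approx(1.0)
        assert report.bland_altman.bias == pytest.approx(100.0)
        assert report.bland_altman.loa_lower == pytest.approx(100.0)

    def test_reversed_ranks(self):
        report = validate_pv_model([1, 2, 3, 4], [9, 8, 7, 6])
        assert report.spearman_r == pytest.approx(-1.0)

    def test_constant_series_reported_undefined(self):
        report = validate_pv_model([3000.0] * 4, [2900, 3000, 3100, 3200])
        assert np.isnan(report.spearman_r)

    def test_per_sex_stratification(self):
        est = [3000, 3100, 3200, 2500, 2600, 2700]
        meas = [2950, 3150, 3180, 2530, 2590, 2760]
        report = validate_pv_model(est, meas, ["male"] * 3 + ["female"] * 3)
        assert set(report.per_sex) == {"male", "female"}
        assert report.per_sex["male"].n == 3

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            validate_pv_model([1, 2, 3], [1, 2])


class TestWeightingIndex:
    def test_collinear_is_one(self):
        pv = np.linspace(2800, 3800, 10)
        assert weighting_index(pv, -0.002 * pv + 20) == pytest.approx(1.0)

    def test_independent_is_near_zero(self):
        rng = np.random.default_rng(3)
        r2 = weighting_index(
            rng.normal(3500, 300, 10_000), rng.normal(15, 1, 10_000)
        )
        assert r2 < 0.01

    def test_equals_squared_pearson(self):
        rng = np.random.default_rng(4)
        pv = rng.normal(3500, 300, 200)
        hb = 18 - 0.001 * pv + rng.normal(0, 0.4, 200)
        r2 = weighting_index(pv, hb)
        assert r2 == pytest.approx(np.corrcoef(pv, hb)[0, 1] ** 2, abs=1e-12)

    def test_constant_series_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            weighting_index([3500.0] * 5, [15.0, 15.1, 14.9, 15.2, 15.0])

    def test_default_per_sex_constants(self):
        assert DEFAULT_WEIGHTS[Sex.MALE] == 0.28
        assert DEFAULT_WEIGHTS[Sex.FEMALE] == 0.42

    def test_slope_sign_exposed(self):
        pv = np.linspace(2800, 3800, 50)
        slope, _, _ = pv_hb_regression(pv, 20 - 0.002 * pv)
        assert slope < 0
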