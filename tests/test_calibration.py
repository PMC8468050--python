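import numpy as np
import pandas as pd
import pytest

import zipfent as z
from zipfent.calibration import SimulationConfig, log_grid


def synthetic_ensemble(D, M, family="zml", rank=1):
    return pd.DataFrame(
        {"family": family, "M": np.asarray(M, float), "rank": rank,
         "D_mean": np.asarray(D, float), "D_sd": 0.0, "trials": 1}
    )


class TestEnsemble:
    def test_equiprobable_binary_mean_distance(self):
        # recurrence of a fair-coin symbol: geometric gaps of mean 2, so
        # the distance (gap + 1) averages 3; the empirically-most-frequent
        # selection pulls it slightly below
        cfg = SimulationConfig(seed=5, trials=30, samples=20_000, M_grid=(2,))
        ens = z.simulate_distance_ensemble("equiprobable", cfg, ranks=(1,))
        assert ens["D_mean"].iloc[0] == pytest.approx(3.0, abs=0.1)

    def test_same_seed_identical(self):
        cfg = SimulationConfig(seed=9, trials=4, samples=5_000, M_grid=(4, 8))
        a = z.simulate_distance_ensemble("zml", cfg)
        b = z.simulate_distance_ensemble("zml", cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_distance_monotone_in_m(self):
        cfg = SimulationConfig(seed=2, trials=10, samples=50_000,
                               M_grid=(5, 10, 20, 40, 80))
        ens = z.simulate_distance_ensemble("zml", cfg).sort_values("M")
        assert np.all(np.diff(ens["D_mean"]) > 0)

    def test_seed_stability_within_three_standard_errors(self):
        cfg_a = SimulationConfig(seed=11, trials=20, samples=50_000, M_grid=(30,))
        cfg_b = SimulationConfig(seed=77, trials=20, samples=50_000, M_grid=(30,))
        a = z.simulate_distance_ensemble("zml", cfg_a).iloc[0]
        b = z.simulate_distance_ensemble("zml", cfg_b).iloc[0]
        se = np.hypot(a["D_sd"] / np.sqrt(a["trials"]),
                      b["D_sd"] / np.sqrt(b["trials"]))
        assert abs(a["D_mean"] - b["D_mean"]) < 3 * se


class TestForwardFit:
    def test_power_parameter_recovery(self):
        D = np.linspace(2, 12, 9)
        model = z.fit_forward_model(
            synthetic_ensemble(D, 2 * D**1.5 + 10), form="power"
        )
        a, b, c = model.params[1]
        assert a == pytest.approx(2.0, abs=1e-6)
        assert b == pytest.approx(1.5, abs=1e-6)
        assert c == pytest.approx(10.0, abs=1e-6)

    def test_identity_fit(self):
        D = np.linspace(3, 50, 12)
        model = z.fit_forward_model(synthetic_ensemble(D, D), form="power")
        a, b, c = model.params[1]
        assert (a, b, c) == pytest.approx((1.0, 1.0, 0.0), abs=1e-6)

    def test_non_monotone_ensemble_rejected(self):
        with pytest.raises(z.CalibrationFitError, match="not strictly increasing"):
            z.fit_forward_model(synthetic_ensemble([3, 5, 4], [10, 20, 30]))

    def test_too_few_points_rejected(self):
        with pytest.raises(z.CalibrationFitError):
            z.fit_forward_model(synthetic_ensemble([3, 5], [10, 20]))

    def test_fitted_curves_strictly_increasing(self):
        cfg = SimulationConfig(seed=3, trials=8, samples=30_000,
                               M_grid=log_grid(8, 80, 8))
        model = z.calibrate("zml", cfg, ranks=(1, 2), form="polynomial")
        for r in (1, 2):
            lo, hi = model.valid_range[r]
            dense = np.linspace(lo, hi, 100)
            vals = [model.predict_M(d, r, warn=False) for d in dense]
            assert np.all(np.diff(vals) > 0)


class TestPredict:
    def test_identity_parameters(self, identity_calib):
        assert identity_calib.predict_M(30.0, 1) == 30.0

    def test_extrapolation_warns_and_flags(self, identity_calib):
        assert identity_calib.extrapolates(0.5, 1)
        with pytest.warns(z.ExtrapolationWarning):
            identity_calib.predict_M(0.5, 1)

    def test_nonpositive_distance_rejected(self, identity_calib):
        with pytest.raises(ValueError):
            identity_calib.predict_M(0.0, 1)

    def test_inverse_closed_form(self):
        calib = z.CalibrationModel("zml", "power", {1: (2.0, 2.0, 1.0)},
                                   {1: (1.0, 10.0)})
        assert calib.predict_D(9.0, 1) == pytest.approx(2.0)

    def test_inverse_identity(self, identity_calib):
        assert identity_calib.predict_D(30.0, 1) == pytest.approx(30.0)

    def test_inverse_below_offset_rejected(self):
        calib = z.CalibrationModel("zml", "power", {1: (2.0, 2.0, 1.0)},
                                   {1: (1.0, 10.0)})
        with pytest.raises(ValueError):
            calib.predict_D(0.5, 1)

    def test_power_roundtrip(self):
        calib = z.CalibrationModel("zml", "power", {1: (1.7, 2.3, 4.0)},
                                   {1: (2.0, 20.0)})
        for D in np.linspace(2.0, 20.0, 15):
            M = calib.predict_M(float(D), 1, warn=False)
            assert calib.predict_D(M, 1) == pytest.approx(float(D), abs=1e-6)

    def test_polynomial_roundtrip(self, zml_calib):
        lo, hi = zml_calib.valid_range[1]
        for D in np.linspace(lo, hi, 10):
            M = zml_calib.predict_M(float(D), 1, warn=False)
            assert zml_calib.predict_D(M, 1) == pytest.approx(float(D), abs=1e-6)


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        calib = z.CalibrationModel("zml", "power", {1: (1.0, 2.0, 3.0)},
                                   {1: (2.0, 9.0)}, {"note": "x"})
        path = tmp_path / "c.json"
        calib.save(path)
        back = z.CalibrationModel.load(path)
        assert back.params == calib.params
        assert back.valid_range == calib.valid_range
        assert back.dist_family == "zml" and back.form == "power"

    def test_seeded_calibration_byte_identical(self):
        cfg = SimulationConfig(seed=4, trials=3, samples=5_000, M_grid=(6, 12, 24))
        a = z.calibrate("zml", cfg, form="power")
        b = z.calibrate("zml", cfg, form="power")
        assert a.to_json() == b.to_json()


class TestDefaultCalibration:
    def test_available_families(self):
        for fam in ("zml", "czml1", "czml2", "equiprobable"):
            model = z.default_calibration(fam)
            assert model.dist_family == fam

    def test_unknown_family(self):
        with pytest.raises(KeyError):
            z.default_calibration("nonesuch")

    def test_self_consistency_on_training_grid(self, zml_calib):
        # the fitted forward model reproduces the grid it was trained on
        ens = zml_calib.metadata["ensemble"]
        for Mv, r, D in zip(ens["M"], ens["rank"], ens["D_mean"]):
            M_hat = zml_calib.predict_M(D, int(r), warn=False)
            assert abs(M_hat - Mv) / Mv <= 0.05
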