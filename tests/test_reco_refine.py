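"""Refined respiration models: per-class least-squares fits and prediction."""

import numpy as np
import pandas as pd
import pytest

from vprmsif import (
    RecoRefineParams,
    TemperatureLimits,
    compare,
    fit_reco_params,
    predict_reco,
    reco_vprm,
)

from conftest import build_field, uniform_vegmap


def _uniform_scene(cls="Grassland", n=64, seed=0):
    """Single-class fields with independent SM/ST/Tair variation."""
    rng = np.random.default_rng(seed)
    shape = (4, 4, n // 16)
    sm = build_field(rng.uniform(0.05, 0.45, shape), units="m3 m-3", name="sm")
    st = build_field(rng.uniform(290, 310, shape), units="K", name="st")
    tair = build_field(rng.uniform(5, 35, shape), units="degC", name="tair")
    return sm, st, tair, uniform_vegmap(sm, cls)


class TestFitRecoParams:
    def test_noiseless_sm_experiment_exact_recovery(self, tropical_params):
        sm, st, tair, vm = _uniform_scene()
        baseline = reco_vprm(tair, vm, tropical_params)
        reco_ref = sm.with_values(
            5000.0 * sm.values + 0.9 * baseline.values, name="reco_ref"
        )
        fitted = fit_reco_params("SM", sm, None, tair, reco_ref, vm, tropical_params)
        coeffs = fitted.coeffs("Grassland")
        assert coeffs["nu"] == pytest.approx(5000.0, abs=1e-8)
        assert coeffs["kappa"] == pytest.approx(0.9, abs=1e-10)

    @pytest.mark.parametrize("experiment", ["SM", "ST", "SMST"])
    def test_identity_model_gives_unit_kappa(self, experiment, tropical_params):
        sm, st, tair, vm = _uniform_scene()
        baseline = reco_vprm(tair, vm, tropical_params)
        reco_ref = tair.with_values(baseline.values, name="reco_ref")
        fitted = fit_reco_params(experiment, sm, st, tair, reco_ref, vm, tropical_params)
        coeffs = fitted.coeffs("Grassland")
        assert coeffs["kappa"] == pytest.approx(1.0, abs=1e-8)
        for name in ("nu", "tau"):
            if name in coeffs:
                assert coeffs[name] == pytest.approx(0.0, abs=1e-8)

    def test_noiseless_smst_recovery_on_scene(self, scene_clean, tropical_params):
        fitted = fit_reco_params(
            "SMST", scene_clean.sm, scene_clean.st, scene_clean.tair,
            scene_clean.reco_ref, scene_clean.vegmap, tropical_params,
        )
        truth = scene_clean.truth_reco.set_index("class")
        for cls in fitted.classes():
            coeffs = fitted.coeffs(cls)
            assert coeffs["tau"] == pytest.approx(truth.loc[cls, "tau0"], abs=1e-8)
            assert coeffs["nu"] == pytest.approx(truth.loc[cls, "nu0"], abs=1e-8)
            assert coeffs["kappa"] == pytest.approx(truth.loc[cls, "kappa0"], abs=1e-8)

    def test_noisy_recovery_within_3_standard_errors(self, scene_noisy, tropical_params):
        from vprmsif import class_mask

        s = scene_noisy
        fitted = fit_reco_params(
            "SMST", s.sm, s.st, s.tair, s.reco_ref, s.vegmap, tropical_params
        )
        baseline = reco_vprm(s.tair, s.vegmap, tropical_params)
        truth = s.truth_reco.set_index("class")
        sigma = s.config.reco_noise
        for cls in fitted.classes():
            sel = np.broadcast_to(class_mask(s.vegmap, cls), s.reco_ref.values.shape)
            ok = sel & ~np.ma.getmaskarray(s.reco_ref.values)
            X = np.column_stack(
                [
                    np.ma.getdata(s.st.values)[ok],
                    np.ma.getdata(s.sm.values)[ok],
                    np.ma.getdata(baseline.values)[ok],
                ]
            )
            se = sigma * np.sqrt(np.diag(np.linalg.inv(X.T @ X)))
            coeffs = fitted.coeffs(cls)
            fit_vec = np.array([coeffs["tau"], coeffs["nu"], coeffs["kappa"]])
            truth_vec = truth.loc[cls, ["tau0", "nu0", "kappa0"]].to_numpy(float)
            assert np.all(np.abs(fit_vec - truth_vec) <= 3 * se), cls

    def test_rank_deficient_design_omitted_with_warning(self, tropical_params):
        sm, st, tair, vm = _uniform_scene()
        baseline = reco_vprm(tair, vm, tropical_params)
        collinear_sm = sm.with_values(2.0 * baseline.values, name="sm")
        reco_ref = tair.with_values(baseline.values, name="reco_ref")
        with pytest.warns(UserWarning, match="collinear"), pytest.raises(ValueError):
            fit_reco_params("SM", collinear_sm, None, tair, reco_ref, vm, tropical_params)

    def test_missing_required_field_rejected(self, tropical_params):
        sm, st, tair, vm = _uniform_scene()
        with pytest.raises(ValueError, match="soil-temperature"):
            fit_reco_params("SMST", sm, None, tair, sm, vm, tropical_params)


class TestPredictReco:
    def test_degenerate_refinement_reduces_to_baseline(self, tropical_params):
        sm, st, tair, vm = _uniform_scene()
        params = RecoRefineParams(
            pd.DataFrame({"class": ["Grassland"], "nu": [0.0], "kappa": [1.0]}), "SM"
        )
        pred = predict_reco("SM", params, sm, None, tair, vm, tropical_params)
        baseline = reco_vprm(tair, vm, tropical_params)
        assert np.ma.allclose(pred.values, np.ma.clip(baseline.values, 0, None))

    def test_smst_with_nu_zero_reproduces_st_experiment(self, tropical_params):
        sm, st, tair, vm = _uniform_scene()
        smst = RecoRefineParams(
            pd.DataFrame(
                {"class": ["Grassland"], "tau": [0.01], "nu": [0.0], "kappa": [0.7]}
            ),
            "SMST",
        )
        st_only = RecoRefineParams(
            pd.DataFrame({"class": ["Grassland"], "tau": [0.01], "kappa": [0.7]}), "ST"
        )
        p1 = predict_reco("SMST", smst, sm, st, tair, vm, tropical_params)
        p2 = predict_reco("ST", st_only, None, st, tair, vm, tropical_params)
        assert np.ma.allclose(p1.values, p2.values)

    def test_hand_evaluated_smst_formula(self, tropical_params):
        sm = build_field(np.full((1, 1, 1), 0.0002), units="m3 m-3", name="sm")
        st = build_field(np.full((1, 1, 1), 300.0), units="K", name="st")
        # choose Tair so the grassland baseline term is exactly 2
        tair = build_field(
            np.full((1, 1, 1), 2.0 / 0.026), units="degC", name="tair"
        )
        vm = uniform_vegmap(sm, "Grassland")
        params = RecoRefineParams(
            pd.DataFrame(
                {"class": ["Grassland"], "tau": [0.01], "nu": [5000.0], "kappa": [0.5]}
            ),
            "SMST",
        )
        pred = predict_reco("SMST", params, sm, st, tair, vm, tropical_params)
        # 0.01*300 + 5000*0.0002 + 0.5*2 = 3 + 1 + 1
        assert pred.values[0, 0, 0] == pytest.approx(5.0)

    def test_all_zero_coefficients_give_zero_field(self, tropical_params):
        sm, st, tair, vm = _uniform_scene()
        params = RecoRefineParams(
            pd.DataFrame(
                {"class": ["Grassland"], "tau": [0.0], "nu": [0.0], "kappa": [0.0]}
            ),
            "SMST",
        )
        pred = predict_reco("SMST", params, sm, st, tair, vm, tropical_params)
        assert np.all(pred.values == 0.0)

    def test_experiment_mismatch_rejected(self, tropical_params):
        sm, st, tair, vm = _uniform_scene()
        params = RecoRefineParams(
            pd.DataFrame({"class": ["Grassland"], "nu": [0.0], "kappa": [1.0]}), "SM"
        )
        with pytest.raises(ValueError, match="experiment"):
            predict_reco("ST", params, sm, st, tair, vm, tropical_params)


class TestNestedModels:
    def test_fitted_rmse_ordering_on_fitting_sample(self, scene_noisy, tropical_params):
        """Least-squares nesting: adding predictors never increases fitted
        RMSE, so SMST <= SM <= baseline and SMST <= ST."""
        s = scene_noisy
        ref = s.reco_ref.values

        def rmse_of(pred):
            return compare(pred.values, ref).rmse

        baseline = reco_vprm(s.tair, s.vegmap, tropical_params)
        rmse = {"baseline": compare(np.ma.clip(baseline.values, 0, None), ref).rmse}
        for exp in ("SM", "ST", "SMST"):
            fitted = fit_reco_params(
                exp, s.sm, s.st, s.tair, s.reco_ref, s.vegmap, tropical_params
            )
            pred = predict_reco(exp, fitted, s.sm, s.st, s.tair, s.vegmap, tropical_params)
            rmse[exp] = rmse_of(pred)
        assert rmse["SMST"] <= rmse["SM"] <= rmse["baseline"]
        assert rmse["SMST"] <= rmse["ST"] <= rmse["baseline"]

    def test_predictions_invariant_to_cell_reordering(self, tropical_params):
        sm, st, tair, vm = _uniform_scene()
        params = RecoRefineParams(
            pd.DataFrame(
                {"class": ["Grassland"], "tau": [0.01], "nu": [100.0], "kappa": [0.5]}
            ),
            "SMST",
        )
        pred = predict_reco("SMST", params, sm, st, tair, vm, tropical_params)
        perm = np.random.default_rng(1).permutation(4)
        sm2 = build_field(np.ma.getdata(sm.values)[:, perm], units="m3 m-3", name="sm")
        st2 = build_field(np.ma.getdata(st.values)[:, perm], units="K", name="st")
        tair2 = build_field(np.ma.getdata(tair.values)[:, perm], units="degC", name="tair")
        pred2 = predict_reco("SMST", params, sm2, st2, tair2, vm, tropical_params)
        assert np.ma.allclose(pred.values[:, perm], pred2.values)
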