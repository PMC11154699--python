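"""Vegetation indices, the three dimensionless scalars, GPP and respiration."""

import numpy as np
import pytest

from vprmsif import (
    GriddedField,
    TemperatureLimits,
    VegMap,
    VPRMParams,
    compute_evi,
    compute_lswi,
    gpp_vprm,
    lswi_max_by_cell,
    p_scale,
    reco_vprm,
    t_scale,
    w_scale,
)

from conftest import build_field, uniform_vegmap

LIMITS = TemperatureLimits()


class TestVegetationIndices:
    def test_evi_zero_when_nir_equals_red(self, one_cell):
        evi = compute_evi(one_cell(0.3), one_cell(0.3), one_cell(0.05))
        assert evi.values[0, 0, 0] == 0.0

    def test_evi_hand_value(self, one_cell):
        # 2.5*(0.4-0.1)/(0.4+0.6-0.375+1) = 0.75/1.625
        evi = compute_evi(one_cell(0.1), one_cell(0.4), one_cell(0.05))
        assert evi.values[0, 0, 0] == pytest.approx(0.75 / 1.625)

    def test_evi_nonpositive_denominator_masked(self, one_cell):
        evi = compute_evi(one_cell(0.0), one_cell(0.0), one_cell(0.5))
        assert np.ma.is_masked(evi.values[0, 0, 0])

    def test_evi_mismatched_grids_rejected(self, one_cell):
        other = build_field(np.zeros((1, 2, 2)), lat0=30.0)
        with pytest.raises(ValueError, match="grid"):
            compute_evi(one_cell(0.1), other, one_cell(0.05))

    def test_lswi_zero_when_bands_equal(self, one_cell):
        assert compute_lswi(one_cell(0.3), one_cell(0.3)).values[0, 0, 0] == 0.0

    def test_lswi_hand_value_and_endpoints(self, one_cell):
        assert compute_lswi(one_cell(0.4), one_cell(0.2)).values[0, 0, 0] == pytest.approx(1 / 3)
        assert compute_lswi(one_cell(0.4), one_cell(0.0)).values[0, 0, 0] == 1.0
        assert compute_lswi(one_cell(0.0), one_cell(0.4)).values[0, 0, 0] == -1.0

    def test_lswi_zero_denominator_masked(self, one_cell):
        assert np.ma.is_masked(compute_lswi(one_cell(0.0), one_cell(0.0)).values[0, 0, 0])


class TestTemperatureScalar:
    def test_unity_at_optimum(self):
        assert t_scale(20.0, LIMITS) == 1.0

    def test_hand_value_at_10C(self):
        # (10*-35)/((10*-35)-100) = 350/450
        assert t_scale(10.0, LIMITS) == pytest.approx(350 / 450)

    @pytest.mark.parametrize("t", [-5.0, 0.0, 45.0, 50.0])
    def test_zero_at_and_outside_limits(self, t):
        assert t_scale(t, LIMITS) == 0.0

    def test_bounded_on_sweep_and_unity_only_at_optimum(self):
        sweep = np.linspace(-20, 60, 801)
        vals = t_scale(sweep, LIMITS)
        assert np.all((vals >= 0) & (vals <= 1))
        assert np.all(vals[sweep != 20.0] < 1.0)
        assert t_scale(20.0, LIMITS) == 1.0

    def test_mask_propagates(self):
        t = np.ma.masked_all(3)
        assert np.ma.getmaskarray(t_scale(t, LIMITS)).all()


class TestPhenologyScalar:
    def test_evergreen_always_unity(self):
        assert p_scale(-0.8, "EvergreenForest") == 1.0

    def test_deciduous_linear_in_lswi(self):
        assert p_scale(0.2, "DeciduousForest") == pytest.approx(0.6)

    def test_other_class_zero(self):
        assert p_scale(0.5, "Other") == 0.0

    def test_max_greenness_pins_to_unity(self):
        assert p_scale(-0.4, "Cropland", is_max_greenness=True) == 1.0

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            p_scale(0.0, "Tundra")


class TestWaterScalar:
    def test_unity_at_maximum(self):
        assert w_scale(0.4, 0.4) == 1.0

    def test_hand_value(self):
        assert w_scale(0.0, 0.5) == pytest.approx(2 / 3)

    def test_zero_at_lower_endpoint(self):
        assert w_scale(-1.0, 0.5) == 0.0

    def test_degenerate_maximum_masked(self):
        assert np.ma.is_masked(w_scale(0.0, -1.0))

    def test_bounded_for_lswi_below_maximum(self):
        lswi = np.linspace(-1, 0.5, 50)
        vals = w_scale(lswi, 0.5)
        assert np.all((vals >= 0) & (vals <= 1))


class TestLswiMax:
    def test_constant_series(self):
        fld = build_field(np.full((3, 1, 1), 0.3))
        assert lswi_max_by_cell(fld)[0, 0] == 0.3

    def test_maximum_of_series(self):
        fld = build_field(np.array([-0.1, 0.4, 0.2])[:, None, None])
        assert lswi_max_by_cell(fld)[0, 0] == 0.4

    def test_all_missing_cell_masked(self):
        fld = build_field(np.ma.masked_all((3, 1, 1)))
        assert np.ma.is_masked(lswi_max_by_cell(fld)[0, 0])


class TestGPP:
    def _inputs(self, evi, lswi, tair, swdown, cls="EvergreenForest"):
        f = build_field
        fields = (
            f(np.full((1, 1, 1), evi), name="evi"),
            f(np.full((1, 1, 1), lswi), name="lswi"),
            f(np.full((1, 1, 1), tair), units="degC", name="tair"),
            f(np.full((1, 1, 1), swdown), units="umol m-2 s-1", name="swdown"),
        )
        return fields, uniform_vegmap(fields[0], cls)

    def test_zero_radiation_gives_zero_gpp(self, tropical_params):
        (evi, lswi, tair, sw), vm = self._inputs(0.5, 0.2, 20.0, 0.0)
        gpp = gpp_vprm(evi, lswi, tair, sw, vm, tropical_params)
        assert gpp.values[0, 0, 0] == 0.0

    def test_worked_example_evergreen_half_saturation(self, tropical_params):
        # all scalars 1 (Topt, evergreen, LSWI=LSWImax), EVI=0.5, SWdown=SWdown0=501
        (evi, lswi, tair, sw), vm = self._inputs(0.5, 0.2, 20.0, 501.0)
        gpp = gpp_vprm(evi, lswi, tair, sw, vm, tropical_params)
        assert gpp.values[0, 0, 0] == pytest.approx(0.21 * 0.5 * 501 * 0.5)

    def test_saturates_at_algebraic_limit(self, tropical_params):
        p = tropical_params["EvergreenForest"]
        (evi, lswi, tair, sw), vm = self._inputs(0.5, 0.2, 20.0, 1e6 * p.swdown0)
        gpp = gpp_vprm(evi, lswi, tair, sw, vm, tropical_params)
        limit = abs(p.lambda_) * 0.5 * p.swdown0
        assert gpp.values[0, 0, 0] == pytest.approx(limit, rel=1e-3)

    def test_monotone_nondecreasing_in_radiation(self, tropical_params):
        previous = -1.0
        for sw in [0.0, 50.0, 200.0, 800.0, 3200.0]:
            (evi, lswi, tair, swf), vm = self._inputs(0.5, 0.2, 20.0, sw)
            val = float(gpp_vprm(evi, lswi, tair, swf, vm, tropical_params).values[0, 0, 0])
            assert val >= previous
            previous = val

    def test_other_class_zero(self, tropical_params):
        (evi, lswi, tair, sw), _ = self._inputs(0.5, 0.2, 20.0, 500.0)
        vm = uniform_vegmap(evi, "Other")
        gpp = gpp_vprm(evi, lswi, tair, sw, vm, tropical_params)
        assert gpp.values[0, 0, 0] == 0.0

    def test_missing_class_parameters_named(self, one_cell):
        partial = VPRMParams(
            VPRMParams.packaged().table.query("`class` != 'Savanna'"), "tropical"
        )
        f = build_field
        evi = f(np.full((1, 1, 1), 0.5))
        vm = uniform_vegmap(evi, "Savanna")
        with pytest.raises(KeyError, match="Savanna"):
            gpp_vprm(evi, evi, evi, evi, vm, partial)

    def test_parameter_sets_differ_only_through_lambda_swdown0(self, scene_clean):
        """Substituting tropical (lambda, swdown0) into the european table
        reproduces the tropical run exactly: alpha/beta do not enter GPP and
        the lambda sign convention is absorbed by the magnitude."""
        from vprmsif import compute_evi, compute_lswi

        s = scene_clean
        evi = compute_evi(s.red, s.nir, s.blue)
        lswi = compute_lswi(s.nir, s.swir)
        trop = VPRMParams.packaged("tropical")
        hybrid_table = VPRMParams.packaged("european").table.copy()
        eur = hybrid_table["set"] == "european"
        for cls in hybrid_table.loc[eur, "class"]:
            sel = eur & (hybrid_table["class"] == cls)
            hybrid_table.loc[sel, "lambda"] = trop[cls].lambda_
            hybrid_table.loc[sel, "swdown0"] = trop[cls].swdown0
        hybrid = VPRMParams(hybrid_table, "european")
        g1 = gpp_vprm(evi, lswi, s.tair, s.swdown, s.vegmap, trop)
        g2 = gpp_vprm(evi, lswi, s.tair, s.swdown, s.vegmap, hybrid)
        assert np.ma.allclose(g1.values, g2.values)


class TestReco:
    def test_grassland_worked_example(self, one_cell, tropical_params):
        tair = one_cell(20.0, units="degC", name="tair")
        vm = uniform_vegmap(tair, "Grassland")
        reco = reco_vprm(tair, vm, tropical_params)
        assert reco.values[0, 0, 0] == pytest.approx(0.026 * 20)

    def test_clamp_at_threshold(self, one_cell, tropical_params):
        tair = one_cell(-10.0, units="degC", name="tair")
        vm = uniform_vegmap(tair, "Grassland")
        reco = reco_vprm(tair, vm, tropical_params)
        # alpha*max(-10, 0) + beta = beta = 0 for the tropical set
        assert reco.values[0, 0, 0] == 0.0

    def test_configurable_threshold(self, one_cell, tropical_params):
        tair = one_cell(-10.0, units="degC", name="tair")
        vm = uniform_vegmap(tair, "Grassland")
        reco = reco_vprm(tair, vm, tropical_params, TemperatureLimits(t_thresh=5.0))
        assert reco.values[0, 0, 0] == pytest.approx(0.026 * 5)

    def test_other_class_zero(self, one_cell, tropical_params):
        tair = one_cell(25.0, units="degC", name="tair")
        vm = uniform_vegmap(tair, "Other")
        assert reco_vprm(tair, vm, tropical_params).values[0, 0, 0] == 0.0
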