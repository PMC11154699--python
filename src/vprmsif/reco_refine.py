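"""Refined ecosystem-respiration models with soil moisture and temperature.

Three experiments extend the baseline air-temperature respiration
B = α·max(Tair, Ttshld) + β with soil predictors:

    SM:    R = ν·SM + κ·B
    ST:    R = τ·ST + κ·B
    SMST:  R = τ·ST + ν·SM + κ·B

The per-class coefficients are adjusted against a reference respiration
field (FLUXNET- or FLUXCOM-like) by ordinary least squares without a free
intercept — κ multiplies the whole baseline term and thereby absorbs its
intercept β.  Units: SM as volumetric fraction (m³ m⁻³), ST in kelvin,
Tair in °C.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .grids import GriddedField, VegMap, class_mask, require_same_grid, require_same_times
from .params import EXPERIMENT_PREDICTORS, RecoRefineParams, TemperatureLimits, VPRMParams
from .vprm import reco_vprm

__all__ = ["fit_reco_params", "predict_reco"]


def _design_columns(experiment: str):
    """(coefficient name, predictor key) pairs, in equation order."""
    order = {"SM": [("nu", "sm")], "ST": [("tau", "st")], "SMST": [("tau", "st"), ("nu", "sm")]}
    return order[experiment] + [("kappa", "baseline")]


def fit_reco_params(
    experiment: str,
    sm: GriddedField | None,
    st: GriddedField | None,
    t_air: GriddedField,
    reco_ref: GriddedField,
    vegmap: VegMap,
    params: VPRMParams,
    limits: TemperatureLimits = TemperatureLimits(),
) -> RecoRefineParams:
    """Fit per-class (ν, τ, κ) for one experiment against reference fluxes.

    Only the fields the experiment uses are required (``sm`` for SM/SMST,
    ``st`` for ST/SMST).  Rank-deficient per-class designs are omitted
    with a warning naming the collinear predictors.
    """
    if experiment not in EXPERIMENT_PREDICTORS:
        raise ValueError("experiment must be one of 'SM', 'ST', 'SMST'")
    predictors: dict[str, GriddedField] = {}
    if "nu" in EXPERIMENT_PREDICTORS[experiment]:
        if sm is None:
            raise ValueError(f"experiment {experiment} requires a soil-moisture field")
        predictors["sm"] = sm
    if "tau" in EXPERIMENT_PREDICTORS[experiment]:
        if st is None:
            raise ValueError(f"experiment {experiment} requires a soil-temperature field")
        predictors["st"] = st
    fields = [t_air, reco_ref, *predictors.values()]
    require_same_grid(*fields)
    require_same_times(*fields)
    predictors["baseline"] = reco_vprm(t_air, vegmap, params, limits)

    columns = _design_columns(experiment)
    rows = []
    for cls in vegmap.present_classes():
        if cls == "Other":
            continue
        sel = np.broadcast_to(class_mask(vegmap, cls), reco_ref.values.shape)
        ok = sel & ~np.ma.getmaskarray(reco_ref.values)
        for f in predictors.values():
            ok = ok & ~np.ma.getmaskarray(f.values)
        y = np.ma.getdata(reco_ref.values)[ok]
        if y.size < len(columns):
            warnings.warn(f"class {cls}: too few samples ({y.size}); omitted")
            continue
        X = np.column_stack(
            [np.ma.getdata(predictors[key].values)[ok] for _, key in columns]
        )
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            names = ", ".join(key for _, key in columns)
            warnings.warn(
                f"class {cls}: rank-deficient design (collinear among {names}); omitted"
            )
            continue
        row = {"class": cls}
        row.update({name: c for (name, _), c in zip(columns, coef)})
        rows.append(row)
    if not rows:
        raise ValueError("no vegetation class yielded a full-rank respiration fit")
    return RecoRefineParams(pd.DataFrame(rows), experiment)


def predict_reco(
    experiment: str,
    refine_params: RecoRefineParams,
    sm: GriddedField | None,
    st: GriddedField | None,
    t_air: GriddedField,
    vegmap: VegMap,
    vprm_params: VPRMParams,
    limits: TemperatureLimits = TemperatureLimits(),
) -> GriddedField:
    """Evaluate a refined respiration model (µmol CO2 m⁻² s⁻¹).

    Floored at 0; ``Other`` cells are 0.  The parameter object's
    experiment tag must match ``experiment``.
    """
    if refine_params.experiment != experiment:
        raise ValueError(
            f"parameters are for experiment {refine_params.experiment!r}, "
            f"not {experiment!r}"
        )
    needs = EXPERIMENT_PREDICTORS[experiment]
    if "nu" in needs and sm is None:
        raise ValueError(f"experiment {experiment} requires a soil-moisture field")
    if "tau" in needs and st is None:
        raise ValueError(f"experiment {experiment} requires a soil-temperature field")
    baseline = reco_vprm(t_air, vegmap, vprm_params, limits)

    out = np.ma.masked_all(t_air.values.shape)
    for cls in vegmap.present_classes():
        sel = np.broadcast_to(class_mask(vegmap, cls), out.shape)
        if cls == "Other":
            out[sel] = 0.0
            continue
        c = refine_params.coeffs(cls)
        pred = c["kappa"] * baseline.values
        if "nu" in c:
            pred = pred + c["nu"] * sm.values
        if "tau" in c:
            pred = pred + c["tau"] * st.values
        out[sel] = np.ma.clip(pred, 0.0, None)[sel]
    return t_air.with_values(
        out, units="umol CO2 m-2 s-1", name=f"reco_vprm_{experiment.lower()}"
    )
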