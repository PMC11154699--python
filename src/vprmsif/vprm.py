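"""Standard light-use-efficiency model: vegetation indices, the three
dimensionless scalars, GPP and ecosystem respiration.

GPP per cell and time step is

    GPP = |λ| · Pscale · Tscale · Wscale · EVI · SWdown / (1 + SWdown/SWdown0)

with the fraction of radiation absorbed by the photosynthetically active
vegetation taken equal to EVI, and respiration is the clamped linear
response R_eco = α · max(Tair, Ttshld) + β.  λ is taken in absolute value so
both sign conventions of the packaged parameter sets yield a positive
uptake magnitude.
"""

from __future__ import annotations

import numpy as np

from .grids import (
    ALL_CLASSES,
    GriddedField,
    VegMap,
    class_mask,
    require_same_grid,
    require_same_times,
)
from .params import TemperatureLimits, VPRMParams

__all__ = [
    "compute_evi",
    "compute_lswi",
    "t_scale",
    "p_scale",
    "w_scale",
    "lswi_max_by_cell",
    "max_greenness_periods",
    "gpp_vprm",
    "reco_vprm",
]


def compute_evi(red: GriddedField, nir: GriddedField, blue: GriddedField) -> GriddedField:
    """Enhanced Vegetation Index from red, NIR and blue reflectance.

    EVI = 2.5 (NIR − Red) / (NIR + 6 Red − 7.5 Blue + 1); cells where any
    band is missing or the denominator is non-positive come back masked.
    """
    require_same_grid(red, nir, blue)
    require_same_times(red, nir, blue)
    denom = nir.values + 6.0 * red.values - 7.5 * blue.values + 1.0
    evi = 2.5 * (nir.values - red.values) / np.ma.masked_less_equal(denom, 0.0)
    return red.with_values(evi, units="1", name="evi")


def compute_lswi(nir: GriddedField, swir: GriddedField) -> GriddedField:
    """Land Surface Water Index (NIR − SWIR) / (NIR + SWIR), masked where
    the denominator is zero."""
    require_same_grid(nir, swir)
    require_same_times(nir, swir)
    denom = np.ma.masked_values(nir.values + swir.values, 0.0, atol=0.0, rtol=0.0)
    lswi = (nir.values - swir.values) / denom
    return nir.with_values(lswi, units="1", name="lswi")


def t_scale(t_air, limits: TemperatureLimits = TemperatureLimits()):
    """Dimensionless temperature scalar of photosynthesis.

    For Tmin < Tair < Tmax,

        Tscale = (Tair−Tmin)(Tair−Tmax) / [(Tair−Tmin)(Tair−Tmax) − (Tair−Topt)²]

    and 0 at or outside [Tmin, Tmax] (photosynthesis absent).  Accepts
    scalars, arrays or masked arrays in °C and preserves masks.
    """
    t = np.ma.asarray(t_air, dtype=float)
    a = (t - limits.t_min) * (t - limits.t_max)
    denom = a - (t - limits.t_opt) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.ma.where(denom != 0, a / denom, 0.0)
    inside = (t > limits.t_min) & (t < limits.t_max)
    scale = np.ma.where(inside, scale, 0.0)
    if np.isscalar(t_air):
        return float(scale)
    return scale


def p_scale(lswi, cls: str, is_max_greenness=False):
    """Phenology (leaf-age) scalar.

    Evergreen forest → 1 always; ``Other`` (water/unclassified) → 0; at the
    time of maximum greenness (full leaf expansion) → 1; otherwise
    (1 + LSWI) / 2.
    """
    if cls not in ALL_CLASSES:
        raise ValueError(f"unknown vegetation class label {cls!r}")
    lswi_arr = np.ma.asarray(lswi, dtype=float)
    if cls == "EvergreenForest":
        out = np.ma.ones_like(lswi_arr)
    elif cls == "Other":
        out = np.ma.zeros_like(lswi_arr)
    else:
        out = np.ma.where(is_max_greenness, 1.0, (1.0 + lswi_arr) / 2.0)
    if np.isscalar(lswi) and np.ndim(is_max_greenness) == 0:
        return float(out)
    return out


def w_scale(lswi, lswi_max):
    """Water-stress scalar (1 + LSWI) / (1 + LSWImax), with LSWImax the
    per-cell annual maximum; masked where LSWImax = −1."""
    lswi_arr = np.ma.asarray(lswi, dtype=float)
    denom = 1.0 + np.ma.asarray(lswi_max, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (1.0 + lswi_arr) / np.ma.masked_values(denom, 0.0, atol=0.0, rtol=0.0)
    if np.isscalar(lswi) and np.isscalar(lswi_max):
        return float(out) if not np.ma.is_masked(out) else np.ma.masked
    return out


def lswi_max_by_cell(lswi: GriddedField, year: int | None = None) -> np.ma.MaskedArray:
    """Per-cell maximum LSWI over the (optionally year-restricted) composites.

    Used as LSWImax in the water-stress scalar; cells with no observations
    come back masked.
    """
    values = lswi.values
    if year is not None and lswi.times is not None:
        sel = (lswi.times >= np.datetime64(f"{year}-01-01")) & (
            lswi.times < np.datetime64(f"{year + 1}-01-01")
        )
        if not sel.any():
            raise ValueError(f"no composites fall in year {year}")
        values = values[sel]
    if lswi.times is None:
        return values.copy()
    return values.max(axis=0)


def max_greenness_periods(evi: GriddedField, frac: float = 0.99) -> np.ndarray:
    """Boolean (time, lat, lon) flag of maximum-greenness composites.

    A composite counts as maximum greenness for a cell when its EVI reaches
    at least ``frac`` of that cell's annual EVI maximum — the full-leaf
    expansion window in which the phenology scalar is pinned to 1.
    """
    peak = evi.values.max(axis=0)
    flag = np.ma.filled(evi.values >= frac * peak, False)
    return np.asarray(flag, dtype=bool)


def _per_class_apply(vegmap: VegMap, classes_needed, params) -> None:
    for cls in classes_needed:
        if cls != "Other" and cls not in params:
            raise KeyError(f"missing parameters for vegetation class {cls!r}")


def gpp_vprm(
    evi: GriddedField,
    lswi: GriddedField,
    t_air: GriddedField,
    swdown: GriddedField,
    vegmap: VegMap,
    params: VPRMParams,
    limits: TemperatureLimits = TemperatureLimits(),
    *,
    lswi_max: np.ma.MaskedArray | None = None,
    max_greenness: np.ndarray | None = None,
) -> GriddedField:
    """Gross primary productivity of the standard model (µmol CO2 m⁻² s⁻¹).

    Parameters are looked up per vegetation class; ``Other`` cells are 0.
    ``lswi_max`` (per-cell annual LSWI maximum) and ``max_greenness``
    (boolean composite flags) are derived from ``lswi`` / ``evi`` when not
    supplied.  Output is floored at 0 and reported as a positive uptake
    magnitude regardless of the λ sign convention of the parameter set.
    """
    require_same_grid(evi, lswi, t_air, swdown)
    require_same_times(evi, lswi, t_air, swdown)
    if vegmap.grid != evi.grid:
        raise ValueError("vegetation map grid does not match the input fields")
    _per_class_apply(vegmap, vegmap.present_classes(), params)

    if lswi_max is None:
        lswi_max = lswi_max_by_cell(lswi)
    if max_greenness is None:
        max_greenness = max_greenness_periods(evi)

    tsc = t_scale(t_air.values, limits)
    wsc = w_scale(lswi.values, lswi_max[np.newaxis] if lswi.times is not None else lswi_max)

    out = np.ma.masked_all(evi.values.shape)
    for cls in vegmap.present_classes():
        mask2d = class_mask(vegmap, cls)
        sel = np.broadcast_to(mask2d, out.shape)
        if cls == "Other":
            out[sel] = 0.0
            continue
        p = params[cls]
        psc = p_scale(lswi.values, cls, is_max_greenness=max_greenness)
        light = swdown.values / (1.0 + swdown.values / p.swdown0)
        gpp = abs(p.lambda_) * psc * tsc * wsc * evi.values * light
        out[sel] = np.ma.clip(gpp, 0.0, None)[sel]
    return evi.with_values(out, units="umol CO2 m-2 s-1", name="gpp_vprm")


def reco_vprm(
    t_air: GriddedField,
    vegmap: VegMap,
    params: VPRMParams,
    limits: TemperatureLimits = TemperatureLimits(),
) -> GriddedField:
    """Baseline ecosystem respiration α·max(Tair, Ttshld) + β per class.

    The clamp at ``limits.t_thresh`` keeps winter respiration from going
    negative.  ``Other`` cells are 0.
    """
    if vegmap.grid != t_air.grid:
        raise ValueError("vegetation map grid does not match the input field")
    _per_class_apply(vegmap, vegmap.present_classes(), params)
    t_clamped = np.ma.maximum(t_air.values, limits.t_thresh)
    out = np.ma.masked_all(t_air.values.shape)
    for cls in vegmap.present_classes():
        mask2d = class_mask(vegmap, cls)
        sel = np.broadcast_to(mask2d, out.shape)
        if cls == "Other":
            out[sel] = 0.0
            continue
        p = params[cls]
        reco = p.alpha * t_clamped + p.beta
        out[sel] = reco[sel]
    return t_air.with_values(out, units="umol CO2 m-2 s-1", name="reco_vprm")
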