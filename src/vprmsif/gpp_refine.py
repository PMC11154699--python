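"""Per-biome refinement of modelled GPP against SIF-based GPP.

The refinement is an affine per-class correction

    GPP_refined = η(vg) · GPP_model + ε(vg)

The default η estimator is the GPP-weighted mean of the SIF-based GPP,

    η(vg) = Σ (GPP_sif · GPP_model) / Σ GPP_model

summed over all cells and composites of the class.  A least-squares slope
through the origin (Σ xy / Σ x²) is available as an alternative.  ε is the
mean residual after η, which makes the refined field's class mean equal
the SIF-based class mean on the fitting sample.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .grids import GriddedField, VegMap, class_mask, require_same_grid, require_same_times
from .params import RefineScalars

__all__ = ["fit_eta", "apply_refinement"]


def fit_eta(
    gpp_sif: GriddedField,
    gpp_vprm: GriddedField,
    vegmap: VegMap,
    *,
    estimator: str = "literal",
) -> RefineScalars:
    """Fit per-class refinement scalars (η, ε).

    ``estimator='literal'`` uses η = Σ(sif·model)/Σ model; ``'slope0'``
    uses the least-squares slope through the origin Σ(sif·model)/Σ model².
    Classes whose model-GPP sum (or sum of squares) is zero are omitted
    with a warning.
    """
    if estimator not in ("literal", "slope0"):
        raise ValueError("estimator must be 'literal' or 'slope0'")
    require_same_grid(gpp_sif, gpp_vprm)
    require_same_times(gpp_sif, gpp_vprm)
    rows = []
    for cls in vegmap.present_classes():
        if cls == "Other":
            continue
        sel = np.broadcast_to(class_mask(vegmap, cls), gpp_sif.values.shape)
        ok = (
            sel
            & ~np.ma.getmaskarray(gpp_sif.values)
            & ~np.ma.getmaskarray(gpp_vprm.values)
        )
        s = np.ma.getdata(gpp_sif.values)[ok]
        v = np.ma.getdata(gpp_vprm.values)[ok]
        if s.size == 0:
            warnings.warn(f"class {cls}: no matched GPP pairs; omitted")
            continue
        denom = v.sum() if estimator == "literal" else (v * v).sum()
        if denom == 0:
            warnings.warn(f"class {cls}: zero model-GPP denominator; omitted")
            continue
        eta = (s * v).sum() / denom
        epsilon = (s - eta * v).mean()
        rows.append({"class": cls, "eta": eta, "epsilon": epsilon, "n": s.size})
    if not rows:
        raise ValueError("no vegetation class had matched GPP pairs")
    return RefineScalars(pd.DataFrame(rows))


def apply_refinement(
    gpp_vprm: GriddedField, vegmap: VegMap, scalars: RefineScalars
) -> GriddedField:
    """Apply η·GPP + ε per class, floored at 0; ``Other`` cells are 0."""
    if vegmap.grid != gpp_vprm.grid:
        raise ValueError("vegetation map grid does not match the GPP field")
    out = np.ma.masked_all(gpp_vprm.values.shape)
    for cls in vegmap.present_classes():
        sel = np.broadcast_to(class_mask(vegmap, cls), out.shape)
        if cls == "Other":
            out[sel] = 0.0
            continue
        eta, epsilon = scalars.scalars(cls)  # raises KeyError if missing
        out[sel] = np.ma.clip(eta * gpp_vprm.values + epsilon, 0.0, None)[sel]
    return gpp_vprm.with_values(out, name=f"{gpp_vprm.name}_refined")
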