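"""Biome-specific linear SIF→GPP conversion and coefficient transfer.

GPP is assumed to vary linearly with SIF within a biome:

    GPP(vg) = γ(vg) · SIF(vg) + C(vg)

Coefficients are established on the GOSIF side; TROPOSIF-side coefficients
follow by dividing both by the cross-sensor factor S(vg), so that the two
routes agree exactly whenever the products differ by exactly that factor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import GriddedField, VegMap, class_mask
from .params import SIFGPPCoeffs, SIFScaling

__all__ = ["gpp_from_sif", "transfer_coeffs"]


def gpp_from_sif(
    sif: GriddedField, vegmap: VegMap, coeffs: SIFGPPCoeffs
) -> GriddedField:
    """Convert a SIF field to GPP with per-class linear coefficients.

    The coefficient product tag must match the field's product (matched
    against ``sif.name``, which carries ``gosif`` or ``troposif`` for
    fields produced by this package).  Output is floored at 0; masked
    cells and ``Other`` cells stay masked.
    """
    if vegmap.grid != sif.grid:
        raise ValueError("vegetation map grid does not match the SIF field")
    if coeffs.product not in sif.name.lower():
        raise ValueError(
            f"coefficients are for product {coeffs.product!r} but the field "
            f"is named {sif.name!r}"
        )
    out = np.ma.masked_all(sif.values.shape)
    for cls in vegmap.present_classes():
        sel = np.broadcast_to(class_mask(vegmap, cls), out.shape)
        if cls == "Other":
            continue
        gamma, c = coeffs.coeffs(cls)
        out[sel] = np.ma.clip(gamma * sif.values + c, 0.0, None)[sel]
    return sif.with_values(
        out, units="umol CO2 m-2 s-1", name=f"gpp_{coeffs.product}"
    )


def transfer_coeffs(gosif_coeffs: SIFGPPCoeffs, scaling: SIFScaling) -> SIFGPPCoeffs:
    """Derive TROPOSIF-side coefficients from GOSIF-side ones.

    γ_trop(vg) = γ_gosif(vg) / S(vg) and C_trop(vg) = C_gosif(vg) / S(vg):
    substituting TROPOSIF = S·GOSIF into the GOSIF-side line gives the same
    GPP, so the conversion is exactly consistent across products.
    """
    if gosif_coeffs.product != "gosif":
        raise ValueError("transfer starts from GOSIF-side coefficients")
    rows = []
    for cls in gosif_coeffs.classes():
        s = scaling.factor(cls)  # raises KeyError if missing
        if s <= 0:
            raise ValueError(f"non-positive scaling factor for class {cls!r}")
        gamma, c = gosif_coeffs.coeffs(cls)
        rows.append({"class": cls, "gamma": gamma / s, "c": c / s})
    return SIFGPPCoeffs(pd.DataFrame(rows), product="troposif")
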