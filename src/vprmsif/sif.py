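"""Harmonization of two SIF products on a common grid and time base.

The OCO-2-derived product (0.05°, here "GOSIF-like") and the TROPOMI
product (0.1°, "TROPOSIF-like") differ by a roughly constant multiplicative
offset per biome (different retrieval wavelengths and upscaling).  A
per-class scaling factor S maps the former onto the latter:

    TROPOSIF(vg) ≈ S(vg) · GOSIF(vg)

S is estimated as the ratio of per-class sums of matched 8-day pairs
(default), which makes the per-class sums of the scaled product and the
target agree exactly; a least-squares slope through the origin is
available as an alternative.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .grids import GriddedField, VegMap, class_mask, require_same_grid, require_same_times
from .params import SIFScaling

__all__ = ["fit_sif_scaling", "apply_sif_scaling"]


def _class_pairs(a: GriddedField, b: GriddedField, vegmap: VegMap, cls: str):
    sel = np.broadcast_to(class_mask(vegmap, cls), a.values.shape)
    ok = sel & ~np.ma.getmaskarray(a.values) & ~np.ma.getmaskarray(b.values)
    return np.ma.getdata(a.values)[ok], np.ma.getdata(b.values)[ok]


def fit_sif_scaling(
    troposif: GriddedField,
    gosif: GriddedField,
    vegmap: VegMap,
    *,
    estimator: str = "ratio_of_sums",
    min_pairs: int = 2,
) -> SIFScaling:
    """Estimate the per-class cross-sensor factor S and pair diagnostics.

    Pairs with either side missing are dropped.  With the default
    ``ratio_of_sums`` estimator S(vg) = Σ troposif / Σ gosif over the
    class's matched pairs; ``slope0`` uses the least-squares slope through
    the origin Σ(t·g)/Σg².  ``r2`` is the squared Pearson correlation of
    the pairs.  Classes with fewer than ``min_pairs`` pairs, or a zero
    denominator, are omitted with a warning.
    """
    if estimator not in ("ratio_of_sums", "slope0"):
        raise ValueError("estimator must be 'ratio_of_sums' or 'slope0'")
    require_same_grid(troposif, gosif)
    require_same_times(troposif, gosif)
    rows = []
    for cls in vegmap.present_classes():
        if cls == "Other":
            continue
        t, g = _class_pairs(troposif, gosif, vegmap, cls)
        if t.size < min_pairs:
            warnings.warn(f"class {cls}: only {t.size} matched pairs; omitted")
            continue
        denom = g.sum() if estimator == "ratio_of_sums" else (g * g).sum()
        if denom == 0:
            warnings.warn(f"class {cls}: zero-sum reference SIF; omitted")
            continue
        s = t.sum() / denom if estimator == "ratio_of_sums" else (t * g).sum() / denom
        if t.std() == 0 or g.std() == 0:
            r2 = np.nan
        else:
            r2 = float(np.corrcoef(g, t)[0, 1]) ** 2
        rows.append({"class": cls, "s": s, "r2": r2, "n": t.size})
    if not rows:
        raise ValueError("no vegetation class had enough matched SIF pairs")
    return SIFScaling(pd.DataFrame(rows))


def apply_sif_scaling(
    gosif: GriddedField, vegmap: VegMap, scaling: SIFScaling
) -> GriddedField:
    """Scale a GOSIF-like field onto the TROPOSIF radiometric level.

    Per cell the output is S(class)·gosif; ``Other`` cells come back
    masked.  A mapped vegetated class without a factor is an error.
    """
    if vegmap.grid != gosif.grid:
        raise ValueError("vegetation map grid does not match the SIF field")
    out = np.ma.masked_all(gosif.values.shape)
    for cls in vegmap.present_classes():
        sel = np.broadcast_to(class_mask(vegmap, cls), out.shape)
        if cls == "Other":
            continue
        s = scaling.factor(cls)  # raises KeyError if missing
        out[sel] = (s * gosif.values)[sel]
    return gosif.with_values(out, name=f"{gosif.name}_scaled")
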