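"""Model–reference comparison metrics and monthly aggregation.

R² is the squared Pearson correlation, RMSE the root-mean-square error,
and MBE the mean bias error with the model-minus-reference sign
convention (an under-predicting model has negative MBE).  These satisfy
the identity RMSE² = MBE² + var(model − reference).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import CompositeCalendar, GriddedField

__all__ = ["EvalMetrics", "compare", "monthly_means"]


@dataclass(frozen=True)
class EvalMetrics:
    """Comparison summary: r2 (NaN when undefined), rmse, mbe, pair count."""

    r2: float
    rmse: float
    mbe: float
    n: int

    def as_dict(self) -> dict:
        return {"r2": self.r2, "rmse": self.rmse, "mbe": self.mbe, "n": self.n}


def compare(model, reference) -> EvalMetrics:
    """Compare two paired series (arrays or masked arrays).

    Pairs with either side missing are dropped; at least two matched pairs
    are required.  When either series has zero variance R² is undefined
    and reported as NaN while RMSE and MBE are still returned.
    """
    m = np.ma.masked_invalid(np.ma.asarray(model, dtype=float)).ravel()
    o = np.ma.masked_invalid(np.ma.asarray(reference, dtype=float)).ravel()
    if m.size != o.size:
        raise ValueError("model and reference series have different lengths")
    ok = ~np.ma.getmaskarray(m) & ~np.ma.getmaskarray(o)
    mm, oo = np.ma.getdata(m)[ok], np.ma.getdata(o)[ok]
    if mm.size < 2:
        raise ValueError(f"need at least 2 matched pairs, got {mm.size}")
    diff = mm - oo
    rmse = float(np.sqrt(np.mean(diff**2)))
    mbe = float(np.mean(diff))
    if mm.std() == 0 or oo.std() == 0:
        r2 = math.nan
    else:
        r2 = float(np.corrcoef(mm, oo)[0, 1]) ** 2
    return EvalMetrics(r2=r2, rmse=rmse, mbe=mbe, n=int(mm.size))


def _month_overlap_days(start: np.datetime64, end: np.datetime64, year: int) -> np.ndarray:
    """Days of [start, end) falling in each calendar month of ``year``."""
    month_edges = np.array(
        [np.datetime64(f"{year}-{m:02d}-01", "D") for m in range(1, 13)]
        + [np.datetime64(f"{year + 1}-01-01", "D")]
    )
    lo = np.maximum(month_edges[:-1], start)
    hi = np.minimum(month_edges[1:], end)
    return np.maximum((hi - lo).astype("timedelta64[D]").astype(int), 0)


def monthly_means(obj, cal: CompositeCalendar) -> pd.Series:
    """Calendar-month means of an 8-day composite series or gridded field.

    A :class:`GriddedField` is first reduced to its spatial-mean series.
    Composites straddling a month boundary are apportioned to both months
    in proportion to the number of days of overlap.  Months with no
    non-missing data come back as NaN.
    """
    if isinstance(obj, GriddedField):
        values = obj.spatial_mean()
        times = obj.times
    else:
        values = np.ma.masked_invalid(np.ma.asarray(obj, dtype=float))
        times = cal.period_starts
    if times is None or values.shape[0] != cal.N_PERIODS:
        raise ValueError("input must carry one value per composite period")
    starts, ends = cal.period_starts, cal.period_ends
    weight_sum = np.zeros(12)
    value_sum = np.zeros(12)
    mask = np.ma.getmaskarray(values)
    data = np.ma.getdata(values)
    for k in range(cal.N_PERIODS):
        if mask[k]:
            continue
        w = _month_overlap_days(starts[k], ends[k], cal.year)
        weight_sum += w
        value_sum += w * data[k]
    out = np.full(12, np.nan)
    nz = weight_sum > 0
    out[nz] = value_sum[nz] / weight_sum[nz]
    return pd.Series(out, index=pd.RangeIndex(1, 13, name="month"), name="monthly_mean")
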