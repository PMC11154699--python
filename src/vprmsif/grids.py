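"""Core grid, time and vegetation-class data model.

All gridded quantities live on a regular geographic (lat/lon) grid with
center-registered cells: a cell with center ``c`` and resolution ``res``
spans the half-open interval ``[c - res/2, c + res/2)``.  This registration
makes 0.05° -> 0.1° nesting exact, which the SIF harmonization step relies
on.  Missing data are carried as numpy masked arrays, never as sentinel
values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "VEG_CLASSES",
    "ALL_CLASSES",
    "Grid",
    "GriddedField",
    "VegMap",
    "CompositeCalendar",
    "regrid_block_mean",
    "aggregate_to_composites",
    "class_mask",
]

#: The seven vegetated biome classes used for per-class parameterisation.
VEG_CLASSES = (
    "Grassland",
    "Cropland",
    "Savanna",
    "Shrubland",
    "DeciduousForest",
    "EvergreenForest",
    "MixedForest",
)

#: Full class vocabulary; ``Other`` absorbs water bodies and unclassified cells.
ALL_CLASSES = VEG_CLASSES + ("Other",)

_REL_TOL = 1e-6


def _check_uniform(centers: np.ndarray, resolution: float, name: str) -> None:
    if centers.ndim != 1 or centers.size == 0:
        raise ValueError(f"{name} centers must be a non-empty 1-D array")
    if centers.size > 1:
        steps = np.diff(centers)
        if np.any(steps <= 0):
            raise ValueError(f"{name} centers must be strictly ascending")
        if not np.allclose(steps, resolution, rtol=_REL_TOL, atol=_REL_TOL * resolution):
            raise ValueError(
                f"{name} centers are not uniformly spaced at resolution {resolution}"
            )


@dataclass(frozen=True)
class Grid:
    """A regular lat/lon grid of center-registered cells.

    Parameters
    ----------
    lat_centers, lon_centers
        Cell-center coordinates in degrees north / east, strictly ascending
        and uniformly spaced at ``resolution``.
    resolution
        Cell size in degrees, identical in both directions.
    """

    lat_centers: np.ndarray
    lon_centers: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "lat_centers", np.asarray(self.lat_centers, dtype=float))
        object.__setattr__(self, "lon_centers", np.asarray(self.lon_centers, dtype=float))
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        _check_uniform(self.lat_centers, self.resolution, "lat")
        _check_uniform(self.lon_centers, self.resolution, "lon")

    @classmethod
    def regular(
        cls, lat_start: float, lon_start: float, nlat: int, nlon: int, resolution: float
    ) -> "Grid":
        """Build a grid from its south-west corner (cell edge) and shape."""
        lats = lat_start + resolution * (np.arange(nlat) + 0.5)
        lons = lon_start + resolution * (np.arange(nlon) + 0.5)
        return cls(lats, lons, resolution)

    @property
    def shape(self) -> tuple[int, int]:
        return self.lat_centers.size, self.lon_centers.size

    @property
    def lat_edges(self) -> np.ndarray:
        return np.concatenate(
            [self.lat_centers - self.resolution / 2, [self.lat_centers[-1] + self.resolution / 2]]
        )

    @property
    def lon_edges(self) -> np.ndarray:
        return np.concatenate(
            [self.lon_centers - self.resolution / 2, [self.lon_centers[-1] + self.resolution / 2]]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Grid):
            return NotImplemented
        return (
            np.isclose(self.resolution, other.resolution, rtol=_REL_TOL)
            and self.shape == other.shape
            and np.allclose(self.lat_centers, other.lat_centers, atol=_REL_TOL * self.resolution)
            and np.allclose(self.lon_centers, other.lon_centers, atol=_REL_TOL * self.resolution)
        )


def _as_masked(values: np.ndarray) -> np.ma.MaskedArray:
    arr = np.ma.masked_invalid(np.ma.asarray(values, dtype=float))
    if arr.mask is np.ma.nomask:
        arr.mask = np.zeros(arr.shape, dtype=bool)
    return arr


@dataclass
class GriddedField:
    """A (time, lat, lon) array of values on a :class:`Grid` with a missing mask.

    ``times`` holds the start date of each layer (composite start dates for
    8-day data, calendar days for daily data) as ``numpy.datetime64[D]``.
    A time-invariant field uses ``times=None`` and a 2-D ``values`` array.
    """

    grid: Grid
    times: np.ndarray | None
    values: np.ma.MaskedArray
    units: str
    name: str

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError("units must be a nonempty string")
        self.values = _as_masked(self.values)
        if self.times is None:
            expected = self.grid.shape
        else:
            self.times = np.asarray(self.times, dtype="datetime64[D]")
            expected = (self.times.size,) + self.grid.shape
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with grid/times {expected}"
            )

    @property
    def ntime(self) -> int:
        return 1 if self.times is None else self.times.size

    def copy(self) -> "GriddedField":
        return replace(
            self,
            times=None if self.times is None else self.times.copy(),
            values=self.values.copy(),
        )

    def with_values(self, values, *, units: str | None = None, name: str | None = None) -> "GriddedField":
        """Same grid/times, new data."""
        return GriddedField(
            grid=self.grid,
            times=None if self.times is None else self.times.copy(),
            values=_as_masked(values),
            units=units if units is not None else self.units,
            name=name if name is not None else self.name,
        )

    def spatial_mean(self) -> np.ma.MaskedArray:
        """Unweighted mean over grid cells, one value per time layer."""
        if self.times is None:
            return np.ma.mean(self.values)
        return self.values.reshape(self.ntime, -1).mean(axis=1)


def require_same_grid(*fields: GriddedField) -> None:
    ref = fields[0].grid
    for f in fields[1:]:
        if f.grid != ref:
            raise ValueError(
                f"fields {fields[0].name!r} and {f.name!r} are not on the same grid"
            )


def require_same_times(*fields: GriddedField) -> None:
    ref = fields[0].times
    for f in fields[1:]:
        same = (ref is None and f.times is None) or (
            ref is not None and f.times is not None and np.array_equal(ref, f.times)
        )
        if not same:
            raise ValueError(
                f"fields {fields[0].name!r} and {f.name!r} do not share time axes"
            )


@dataclass
class VegMap:
    """Per-cell biome class labels on a :class:`Grid`.

    Labels come from the fixed 8-class vocabulary :data:`ALL_CLASSES`;
    internally the map is stored as integer codes indexing that tuple.
    """

    grid: Grid
    codes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int16)
        if self.codes.shape != self.grid.shape:
            raise ValueError("class codes shape does not match grid")
        if self.codes.min() < 0 or self.codes.max() >= len(ALL_CLASSES):
            raise ValueError("class codes outside vocabulary range")

    @classmethod
    def from_labels(cls, grid: Grid, labels: np.ndarray) -> "VegMap":
        labels = np.asarray(labels)
        lookup = {name: i for i, name in enumerate(ALL_CLASSES)}
        try:
            codes = np.vectorize(lookup.__getitem__, otypes=[np.int16])(labels)
        except KeyError as exc:
            raise ValueError(f"unknown vegetation class label {exc.args[0]!r}") from None
        return cls(grid, codes)

    @classmethod
    def uniform(cls, grid: Grid, label: str) -> "VegMap":
        if label not in ALL_CLASSES:
            raise ValueError(f"unknown vegetation class label {label!r}")
        return cls(grid, np.full(grid.shape, ALL_CLASSES.index(label), dtype=np.int16))

    @property
    def labels(self) -> np.ndarray:
        return np.asarray(ALL_CLASSES, dtype=object)[self.codes]

    def present_classes(self) -> list[str]:
        return [ALL_CLASSES[c] for c in np.unique(self.codes)]


def class_mask(vegmap: VegMap, cls: str) -> np.ndarray:
    """Boolean (lat, lon) mask, true exactly where the map equals ``cls``."""
    if cls not in ALL_CLASSES:
        raise ValueError(f"unknown vegetation class label {cls!r}")
    return vegmap.codes == ALL_CLASSES.index(cls)


@dataclass(frozen=True)
class CompositeCalendar:
    """The MODIS-style 8-day composite calendar for one year.

    Periods restart at day-of-year 1 every year: starts fall on DOY 1, 9,
    17, ..., 361 — 46 periods, the last spanning 5 days (6 in leap years).
    """

    year: int

    N_PERIODS = 46

    @property
    def period_starts(self) -> np.ndarray:
        jan1 = np.datetime64(f"{self.year}-01-01", "D")
        return jan1 + 8 * np.arange(self.N_PERIODS)

    @property
    def period_ends(self) -> np.ndarray:
        """Exclusive end date of each period."""
        next_jan1 = np.datetime64(f"{self.year + 1}-01-01", "D")
        return np.minimum(self.period_starts + 8, next_jan1)


def regrid_block_mean(src: GriddedField, dst_grid: Grid) -> GriddedField:
    """Block-average a fine field onto a coarser, exactly nesting grid.

    Each coarse cell value is the mean of its non-missing fine cells; a
    coarse cell is missing iff all its fine cells are missing.  The domain
    mean is conserved on fully observed data.
    """
    ratio = dst_grid.resolution / src.grid.resolution
    factor = int(round(ratio))
    if factor < 1 or abs(ratio - factor) > _REL_TOL * factor:
        raise ValueError(
            f"destination resolution {dst_grid.resolution}° is not an integer "
            f"multiple of source resolution {src.grid.resolution}°"
        )
    ny_f, nx_f = src.grid.shape
    ny_c, nx_c = dst_grid.shape
    edges_align = (
        ny_f == factor * ny_c
        and nx_f == factor * nx_c
        and np.isclose(src.grid.lat_edges[0], dst_grid.lat_edges[0], atol=1e-6)
        and np.isclose(src.grid.lon_edges[0], dst_grid.lon_edges[0], atol=1e-6)
    )
    if not edges_align:
        raise ValueError(
            f"grids at {src.grid.resolution}° and {dst_grid.resolution}° do not nest: "
            "cell edges are not aligned"
        )
    vals = src.values if src.times is not None else src.values[np.newaxis]
    nt = vals.shape[0]
    blocks = vals.reshape(nt, ny_c, factor, nx_c, factor)
    # flatten each factor×factor block so the mean runs over all its
    # non-missing fine cells at once (a mean of row means would weight
    # partially observed rows wrongly)
    blocks = blocks.transpose(0, 1, 3, 2, 4).reshape(nt, ny_c, nx_c, factor * factor)
    coarse = blocks.mean(axis=3)
    if src.times is None:
        coarse = coarse[0]
    return GriddedField(dst_grid, src.times, coarse, src.units, src.name)


def aggregate_to_composites(daily: GriddedField, cal: CompositeCalendar) -> GriddedField:
    """Average daily layers into the 46-period 8-day composite calendar.

    Each composite is the mean of the non-missing daily values whose dates
    fall in ``[start, start + 8 d)`` (last period truncated at year end);
    it is missing where no daily data exist.
    """
    if daily.times is None or daily.times.size == 0:
        raise ValueError("daily input has no time layers to aggregate")
    year_start = np.datetime64(f"{cal.year}-01-01", "D")
    year_end = np.datetime64(f"{cal.year + 1}-01-01", "D")
    if daily.times.min() < year_start or daily.times.max() >= year_end:
        raise ValueError(f"daily timestamps fall outside calendar year {cal.year}")
    starts, ends = cal.period_starts, cal.period_ends
    ny, nx = daily.grid.shape
    out = np.ma.masked_all((cal.N_PERIODS, ny, nx))
    for k in range(cal.N_PERIODS):
        sel = (daily.times >= starts[k]) & (daily.times < ends[k])
        if sel.any():
            out[k] = daily.values[sel].mean(axis=0)
    return GriddedField(daily.grid, starts, out, daily.units, daily.name)
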