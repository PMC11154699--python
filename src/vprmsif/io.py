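"""NetCDF and CSV interfaces.

Gridded fields travel as CF-style NetCDF (classic format through the
scipy backend) with ``lat``/``lon``/``time`` coordinate variables and a
``units`` attribute; vegetation maps as NetCDF integer class codes with
the legend embedded as a JSON attribute.  Parameter tables are plain CSV
handled by the classes in :mod:`vprmsif.params`.
"""

from __future__ import annotations

import json

import numpy as np
import xarray as xr

from .grids import ALL_CLASSES, Grid, GriddedField, VegMap

__all__ = ["write_field", "read_field", "write_vegmap", "read_vegmap"]

_ENGINE = "scipy"


def _grid_from_coords(lat: np.ndarray, lon: np.ndarray) -> Grid:
    res = float(np.diff(lat).mean()) if lat.size > 1 else float(np.diff(lon).mean())
    return Grid(lat, lon, res)


def field_to_dataset(fld: GriddedField) -> xr.Dataset:
    coords = {"lat": fld.grid.lat_centers, "lon": fld.grid.lon_centers}
    if fld.times is not None:
        coords["time"] = fld.times.astype("datetime64[ns]")
        dims = ("time", "lat", "lon")
    else:
        dims = ("lat", "lon")
    data = np.ma.filled(fld.values.astype(float), np.nan)
    da = xr.DataArray(data, coords=coords, dims=dims, name=fld.name)
    da.attrs["units"] = fld.units
    da.lat.attrs.update(units="degrees_north", standard_name="latitude")
    da.lon.attrs.update(units="degrees_east", standard_name="longitude")
    ds = da.to_dataset()
    ds.attrs["resolution_degrees"] = fld.grid.resolution
    return ds


def write_field(fld: GriddedField, path) -> None:
    """Write one gridded field to a NetCDF file (missing cells as NaN)."""
    field_to_dataset(fld).to_netcdf(path, engine=_ENGINE)


def read_field(path, name: str | None = None) -> GriddedField:
    """Read a gridded field back; ``name`` selects among several variables."""
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds = ds.load()
    names = [v for v in ds.data_vars if v not in ("lat", "lon", "time")]
    if name is None:
        if len(names) != 1:
            raise ValueError(f"file has variables {names}; specify one")
        name = names[0]
    da = ds[name]
    grid = _grid_from_coords(da.lat.values, da.lon.values)
    times = (
        da.time.values.astype("datetime64[D]") if "time" in da.dims else None
    )
    values = np.ma.masked_invalid(da.values)
    units = da.attrs.get("units", "1")
    return GriddedField(grid, times, values, units, name)


def write_vegmap(vegmap: VegMap, path) -> None:
    """Write a vegetation-class map as integer codes plus a JSON legend."""
    ds = xr.Dataset(
        {"veg_class": (("lat", "lon"), vegmap.codes.astype(np.int16))},
        coords={"lat": vegmap.grid.lat_centers, "lon": vegmap.grid.lon_centers},
    )
    ds["veg_class"].attrs["legend"] = json.dumps(
        {str(i): cls for i, cls in enumerate(ALL_CLASSES)}
    )
    ds.attrs["resolution_degrees"] = vegmap.grid.resolution
    ds.to_netcdf(path, engine=_ENGINE)


def read_vegmap(path) -> VegMap:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds = ds.load()
    da = ds["veg_class"]
    legend = json.loads(da.attrs["legend"])
    codes = da.values.astype(np.int16)
    # remap through the legend in case class order differs from ours
    remap = {int(k): ALL_CLASSES.index(v) for k, v in legend.items()}
    out = np.vectorize(remap.__getitem__, otypes=[np.int16])(codes)
    grid = _grid_from_coords(da.lat.values, da.lon.values)
    return VegMap(grid, out)
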