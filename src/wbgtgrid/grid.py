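"""Grid pipeline: apply the point thermal formulas over (time, lat, lon)
stacks and build the aggregates used for heat-stress mapping — daily
maxima and monthly means of daily maxima — plus land-sea masking and
CF-style NetCDF I/O.

Internal conventions: hourly UTC timestamps, latitude ascending, longitude
in [-180, 180), all temperatures stored in Kelvin on input grids and in
deg C on WBGT outputs. Files are written as NetCDF3 classic via xarray's
scipy backend.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr

from .constants import DEFAULT_CONSTANTS, KELVIN_OFFSET, ThermalConstants
from . import thermal

__all__ = [
    "DEFAULT_VARMAP",
    "read_meteo",
    "read_station_csv",
    "compute_wbgt_grid",
    "daily_max",
    "monthly_mean_of_daily_max",
    "apply_land_mask",
    "write_fields",
]

#: Default mapping from internal names to ERA5-style file variable names.
DEFAULT_VARMAP: dict[str, str] = {
    "ta": "t2m",
    "td": "d2m",
    "va": "si10",
    "tmrt": "mrt",
    "lsm": "lsm",
}

_KELVIN_UNITS = {"k", "kelvin", "degk", "deg_k"}
_CELSIUS_UNITS = {"degc", "deg_c", "celsius", "c", "degree_celsius", "degrees_celsius", "°c"}
_SPEED_UNITS = {"m/s", "m s-1", "m s**-1", "ms-1", "meters per second", "m.s-1"}


def _to_kelvin(da: xr.DataArray, name: str) -> xr.DataArray:
    units = str(da.attrs.get("units", "K")).strip().lower()
    if units in _KELVIN_UNITS:
        out = da
    elif units in _CELSIUS_UNITS:
        out = da + KELVIN_OFFSET
    else:
        raise ValueError(f"unknown temperature units {units!r} on variable {name!r}")
    out = out.copy()
    out.attrs["units"] = "K"
    return out


def read_meteo(path: str | Path, varmap: Mapping[str, str] | None = None) -> xr.Dataset:
    """Read an hourly meteorological grid from NetCDF.

    Returns a dataset with variables ``ta, td, tmrt`` (K), ``va`` (m/s)
    and optionally ``lsm`` (land fraction), on normalized coordinates
    (time, lat ascending, lon in [-180, 180)). ``varmap`` maps internal
    names to file variable names; wind may alternatively be supplied as
    components ``u10``/``v10`` which are combined as sqrt(u**2 + v**2).
    """
    vm = dict(DEFAULT_VARMAP)
    if varmap:
        vm.update(varmap)
    ds = xr.open_dataset(path).load()

    # coordinate names: accept latitude/longitude aliases
    renames = {}
    for cand, target in (("latitude", "lat"), ("longitude", "lon"), ("valid_time", "time")):
        if cand in ds.coords and target not in ds.coords:
            renames[cand] = target
    if renames:
        ds = ds.rename(renames)
    for coord in ("time", "lat", "lon"):
        if coord not in ds.coords:
            raise ValueError(f"input file lacks coordinate {coord!r}")

    out = {}
    for internal in ("ta", "td", "tmrt"):
        fname = vm[internal]
        if fname not in ds:
            raise ValueError(f"missing variable {internal!r} (looked for {fname!r})")
        out[internal] = _to_kelvin(ds[fname], internal)

    wname = vm["va"]
    if wname in ds:
        va = ds[wname]
        units = str(va.attrs.get("units", "m s**-1")).strip().lower()
        if units not in _SPEED_UNITS:
            raise ValueError(f"unknown wind units {units!r} on variable {wname!r}")
    elif "u10" in ds and "v10" in ds:
        va = np.hypot(ds["u10"], ds["v10"])
    else:
        raise ValueError(f"missing variable 'va' (looked for {wname!r} or u10/v10)")
    va = va.copy()
    va.attrs["units"] = "m s**-1"
    out["va"] = va

    if vm.get("lsm") and vm["lsm"] in ds:
        out["lsm"] = ds[vm["lsm"]]

    grid = xr.Dataset(out)

    # normalize coordinates: lon to [-180, 180), lat ascending, time sorted
    lon = ((grid["lon"] + 180.0) % 360.0) - 180.0
    grid = grid.assign_coords(lon=lon).sortby("lon")
    if grid["lat"].size > 1 and float(grid["lat"][0]) > float(grid["lat"][-1]):
        grid = grid.sortby("lat")
    grid = grid.sortby("time")
    return grid


def read_station_csv(path: str | Path) -> pd.DataFrame:
    """Read a station time series CSV with columns time, ta, td, va, tmrt
    (temperatures in K, wind in m/s). Returns a time-indexed DataFrame."""
    df = pd.read_csv(path, parse_dates=["time"])
    required = {"time", "ta", "td", "va", "tmrt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"station CSV missing columns: {sorted(missing)}")
    return df.set_index("time").sort_index()


def compute_wbgt_grid(
    grid: xr.Dataset,
    method: str = "brimicombe",
    consts: ThermalConstants = DEFAULT_CONSTANTS,
) -> xr.Dataset:
    """Compute a WBGT stack (deg C) plus validity flags over a grid.

    Purely cell-wise: the result at each (time, lat, lon) equals the point
    computation on that cell's values. Missing inputs propagate to NaN.
    """
    state = thermal.AirState(
        ta=grid["ta"].values, td=grid["td"].values,
        va=grid["va"].values, tmrt=grid["tmrt"].values,
    )
    if method == "brimicombe":
        comp = thermal.wbgt_brimicombe(state, consts)
    elif method == "acsm87":
        comp = thermal.wbgt_acsm87_from_state(state, consts)
    else:
        raise ValueError(f"unknown method {method!r}")

    dims = grid["ta"].dims
    coords = grid["ta"].coords
    ds = xr.Dataset(
        {
            "wbgt": (dims, np.asarray(comp.wbgt, dtype=float)),
            "valid": (dims, np.asarray(comp.valid, dtype=bool)),
        },
        coords=coords,
    )
    if method == "brimicombe":
        ds["tw"] = (dims, np.asarray(comp.tw, dtype=float))
        ds["tg"] = (dims, np.asarray(comp.tg, dtype=float))
    for name in ("wbgt", "tw", "tg"):
        if name in ds:
            ds[name].attrs["units"] = "degC"
    ds.attrs["method"] = method
    for key, val in consts.to_dict().items():
        ds.attrs[f"const_{key}"] = str(val)
    return ds


def daily_max(stack: xr.DataArray, tz_offset_hours: float = 0.0) -> xr.DataArray:
    """Cell-wise daily maximum over the hours of each calendar day.

    Days are UTC by default; ``tz_offset_hours`` shifts timestamps before
    binning for users who want local-solar days. Hours with missing values
    are ignored unless the whole day is missing.
    """
    if stack.sizes.get("time", 0) == 0:
        raise ValueError("empty time axis")
    da = stack
    if tz_offset_hours:
        da = da.assign_coords(time=da["time"] + pd.Timedelta(hours=tz_offset_hours))
    out = da.resample(time="1D").max(skipna=True)
    out.attrs = dict(stack.attrs)
    out.attrs["cell_methods"] = "time: maximum (interval: 1 day)"
    return out


def monthly_mean_of_daily_max(daily: xr.DataArray) -> xr.DataArray:
    """Arithmetic mean over the daily-maximum fields present.

    The canonical heat-stress map quantity: mean over the month of each
    cell's daily maximum WBGT.
    """
    if daily.sizes.get("time", 0) == 0:
        raise ValueError("no daily fields to average")
    out = daily.mean("time", skipna=True)
    out.attrs = dict(daily.attrs)
    out.attrs["cell_methods"] = "time: maximum (interval: 1 day) time: mean over days"
    return out


def apply_land_mask(
    field: xr.DataArray | xr.Dataset,
    land_fraction: xr.DataArray,
    threshold: float = 0.5,
):
    """Mask out sea cells: values where land fraction < threshold become NaN."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    return field.where(land_fraction >= threshold)


def write_fields(fields: xr.Dataset | xr.DataArray, path: str | Path) -> None:
    """Write fields to NetCDF (classic format via the scipy backend).

    Booleans are stored as int8 (NetCDF3 has no bool type); NaN is the
    declared fill value for floats.
    """
    if isinstance(fields, xr.DataArray):
        fields = fields.to_dataset(name=fields.name or "field")
    enc = {}
    ds = fields
    for name, var in ds.data_vars.items():
        if var.dtype == bool:
            ds = ds.assign({name: var.astype("i1")})
        elif np.issubdtype(var.dtype, np.floating):
            enc[name] = {"_FillValue": np.nan}
    ds.to_netcdf(path, engine="scipy", encoding=enc)
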