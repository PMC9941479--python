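"""Comparison machinery: ISO heat-stress categorization, anomaly fields,
mean absolute error (overall and over the heat-stress subset), linear
fit / R-squared, category differences, and station-versus-grid checks.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import xarray as xr

from . import grid as gridmod
from .constants import DEFAULT_CONSTANTS, KELVIN_OFFSET

__all__ = [
    "CATEGORY_LABELS",
    "HEAT_STRESS_THRESHOLD",
    "ComparisonStats",
    "categorize",
    "categorize_field",
    "anomaly",
    "comparison_stats",
    "category_difference",
    "station_compare",
]

#: Recommended maximum workload per ISO-derived WBGT category.
CATEGORY_LABELS = {
    0: "no recommendations",
    1: "very heavy work (45/15 min work/rest)",
    2: "heavy work (30/15)",
    3: "moderate work (30/30)",
    4: "light work (15/45)",
    5: "resting only",
}

#: WBGT above this (deg C) counts as heat stress (category 1 onwards).
HEAT_STRESS_THRESHOLD = 23.0

# Category bin edges (deg C). Left-closed except the top: 33.0 itself is
# still category 4 ("light"); only strictly above 33 is category 5, the
# critical health threshold.
_EDGES = np.array([23.0, 25.0, 28.0, 30.0, 33.0])


def categorize(wbgt_c):
    """ISO heat-stress category 0-5 for WBGT in deg C.

    <23 -> 0, [23,25) -> 1, [25,28) -> 2, [28,30) -> 3, [30,33] -> 4,
    >33 -> 5. NaN propagates as NaN (use the float output's NaNs; integer
    codes are returned where all inputs are finite).
    """
    w = np.asarray(wbgt_c, dtype=float)
    code = np.digitize(w, _EDGES, right=False).astype(float)
    # left-closed bins put exactly 33.0 in bin 5; the top interval is
    # closed at 33 (category 4), so pull the boundary back
    code = np.where(w == _EDGES[-1], 4.0, code)
    code = np.where(np.isnan(w), np.nan, code)
    if code.ndim == 0:
        return float("nan") if np.isnan(code) else int(code)
    return code


def categorize_field(field: xr.DataArray) -> xr.DataArray:
    """Cell-wise categorization of a WBGT field; NaN cells stay NaN."""
    out = xr.apply_ufunc(lambda v: np.asarray(categorize(v), dtype=float), field)
    out.attrs = {"long_name": "heat stress category", "units": "1"}
    return out


def anomaly(candidate: xr.DataArray, reference: xr.DataArray) -> xr.DataArray:
    """Candidate minus reference (deg C): negative where the benchmark
    (reference) is higher than the approximation under test."""
    _check_same_grid(candidate, reference)
    out = candidate - reference
    out.attrs = {"long_name": "WBGT anomaly (candidate - reference)", "units": "degC"}
    return out


def category_difference(candidate_cat: xr.DataArray, reference_cat: xr.DataArray) -> xr.DataArray:
    """Integer category difference, candidate code minus reference code."""
    _check_same_grid(candidate_cat, reference_cat)
    out = candidate_cat - reference_cat
    out.attrs = {"long_name": "heat stress category difference", "units": "1"}
    return out


@dataclasses.dataclass
class ComparisonStats:
    """Agreement statistics between a candidate and a reference WBGT set.

    mae_all/mae_heat in deg C (heat subset: reference strictly above the
    threshold); r2 is the squared Pearson correlation; slope/intercept the
    ordinary least-squares fit of candidate on reference. r2, slope and
    intercept are NaN when fewer than two pairs or zero variance.
    """

    mae_all: float
    mae_heat: float
    r2: float
    slope: float
    intercept: float
    n_all: int
    n_heat: int
    heat_threshold: float = HEAT_STRESS_THRESHOLD

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(self)])


def comparison_stats(
    candidate,
    reference,
    heat_threshold: float = HEAT_STRESS_THRESHOLD,
) -> ComparisonStats:
    """MAE (all pairs and the heat-stress subset of the reference), R²,
    and the least-squares line of candidate on reference.

    Accepts arrays or DataArrays on the same grid; pairs with a missing
    value on either side are dropped.
    """
    cand = np.asarray(getattr(candidate, "values", candidate), dtype=float).ravel()
    ref = np.asarray(getattr(reference, "values", reference), dtype=float).ravel()
    if cand.shape != ref.shape:
        raise ValueError("candidate and reference shapes differ")
    ok = np.isfinite(cand) & np.isfinite(ref)
    cand, ref = cand[ok], ref[ok]
    n_all = cand.size

    mae_all = float(np.mean(np.abs(cand - ref))) if n_all else float("nan")
    heat = ref > heat_threshold
    n_heat = int(heat.sum())
    mae_heat = float(np.mean(np.abs(cand[heat] - ref[heat]))) if n_heat else float("nan")

    if n_all >= 2 and np.ptp(ref) > 0 and np.ptp(cand) > 0:
        r = np.corrcoef(ref, cand)[0, 1]
        r2 = float(r * r)
        slope, intercept = (float(v) for v in np.polyfit(ref, cand, 1))
    else:
        r2 = slope = intercept = float("nan")
    return ComparisonStats(mae_all, mae_heat, r2, slope, intercept, n_all, n_heat, heat_threshold)


def station_compare(
    gridded: xr.DataArray,
    station: pd.Series | pd.DataFrame,
    lat: float,
    lon: float,
    heat_threshold: float = HEAT_STRESS_THRESHOLD,
) -> ComparisonStats:
    """Compare a gridded WBGT stack against a station WBGT series.

    Extracts the nearest grid cell (no interpolation), inner-joins on
    timestamps, takes daily maxima of both series and runs
    ``comparison_stats`` on the paired days. The station series is the
    reference.
    """
    if isinstance(station, pd.DataFrame):
        if "wbgt" not in station.columns:
            raise ValueError("station DataFrame needs a 'wbgt' column")
        station = station["wbgt"]
    lat_min, lat_max = float(gridded["lat"].min()), float(gridded["lat"].max())
    lon_min, lon_max = float(gridded["lon"].min()), float(gridded["lon"].max())
    if not (lat_min <= lat <= lat_max and lon_min <= lon <= lon_max):
        raise ValueError("station coordinates outside grid bounds")

    cell = gridded.sel(lat=lat, lon=lon, method="nearest")
    cell_series = cell.to_series()
    joined = pd.DataFrame({"grid": cell_series, "station": station}).dropna()
    if joined.empty:
        raise ValueError("no temporal overlap between grid and station")

    daily = joined.groupby(joined.index.floor("D")).max()
    return comparison_stats(daily["grid"].values, daily["station"].values, heat_threshold)


def _check_same_grid(a: xr.DataArray, b: xr.DataArray) -> None:
    if a.shape != b.shape:
        raise ValueError("fields are on different grids")
    for coord in ("lat", "lon"):
        if coord in a.coords and coord in b.coords:
            if not np.array_equal(a[coord].values, b[coord].values):
                raise ValueError(f"fields differ in coordinate {coord!r}")
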