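"""Seeded synthetic meteorological fixtures.

Generates hourly (time, lat, lon) grids with the gross structure the WBGT
method assumes — a sinusoidal diurnal temperature cycle, a dew-point
depression below air temperature, a daytime mean-radiant-temperature
excess, non-negative wind — plus station series sampled from a grid cell
with optional observation noise and gaps. Purely for exercising the
pipeline: Gaussian cell-independent noise, no spatial correlation, no
radiative transfer, no real climatology.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
import pandas as pd
import xarray as xr

__all__ = ["SyntheticConfig", "generate_grid", "generate_station"]


@dataclasses.dataclass
class SyntheticConfig:
    """Parameters of the synthetic hourly grid.

    Defaults emulate a warm-humid month on a small grid: mean temperature
    300 K with a 6 K diurnal swing, dew points a few K below air
    temperature, light-to-moderate wind, and a daytime radiant excess of
    up to 15 K over air temperature (clear-sky sun on a globe).
    """

    seed: int = 0
    n_lat: int = 8
    n_lon: int = 8
    n_days: int = 31
    base_t: float = 300.0          # mean air temperature, K
    diurnal_amp: float = 6.0       # half-range of the diurnal cycle, K
    spatial_amp: float = 3.0       # amplitude of the smooth spatial gradient, K
    noise_sd: float = 0.5          # per-cell/hour Gaussian noise, K
    dewpoint_depression: float = 5.0   # mean Td depression below Ta, K
    dewpoint_spread: float = 2.0       # spread of the depression, K
    wind_mean: float = 3.0         # m/s
    wind_spread: float = 2.0       # m/s, truncated at zero
    mrt_day_boost: float = 15.0    # max daytime TMRT excess over Ta, K
    mrt_noise_sd: float = 1.0      # K
    land_fraction_pattern: Literal["all_land", "checkerboard", "coastal"] = "all_land"
    start: str = "2003-07-01"
    lat0: float = 5.0
    lon0: float = 10.0
    dlat: float = 0.25
    dlon: float = 0.25

    def __post_init__(self) -> None:
        if min(self.n_lat, self.n_lon, self.n_days) < 1:
            raise ValueError("grid sizes and day count must be >= 1")
        for name in ("diurnal_amp", "noise_sd", "wind_spread", "mrt_day_boost"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _land_fraction(cfg: SyntheticConfig) -> np.ndarray:
    if cfg.land_fraction_pattern == "all_land":
        return np.ones((cfg.n_lat, cfg.n_lon))
    if cfg.land_fraction_pattern == "checkerboard":
        ii, jj = np.indices((cfg.n_lat, cfg.n_lon))
        return ((ii + jj) % 2).astype(float)
    if cfg.land_fraction_pattern == "coastal":
        # land in the west fading to sea in the east
        frac = np.linspace(1.0, 0.0, cfg.n_lon)
        return np.tile(frac, (cfg.n_lat, 1))
    raise ValueError(f"unknown land_fraction_pattern {cfg.land_fraction_pattern!r}")


def generate_grid(cfg: SyntheticConfig) -> xr.Dataset:
    """Generate a deterministic synthetic hourly meteorological grid.

    Same config and seed give bit-identical output. Variables: ta, td,
    tmrt (K), va (m/s), lsm (land fraction).
    """
    rng = np.random.default_rng(cfg.seed)
    n_t = cfg.n_days * 24
    time = pd.date_range(cfg.start, periods=n_t, freq="h")
    lat = cfg.lat0 + cfg.dlat * np.arange(cfg.n_lat)
    lon = cfg.lon0 + cfg.dlon * np.arange(cfg.n_lon)

    hour = (np.arange(n_t) % 24).astype(float)
    # solar hour angle by longitude; peak insolation at local hour 12,
    # temperature lags by ~2 h
    local_hour = hour[:, None, None] + lon[None, None, :] / 15.0
    diurnal = np.sin(2 * np.pi * (local_hour - 8.0) / 24.0)
    spatial = cfg.spatial_amp * np.cos(np.deg2rad(lat))[None, :, None] * np.ones(
        (1, 1, cfg.n_lon)
    )

    shape = (n_t, cfg.n_lat, cfg.n_lon)
    ta = (
        cfg.base_t
        + cfg.diurnal_amp * diurnal
        + spatial
        + rng.normal(0.0, cfg.noise_sd, shape)
    )
    depression = np.abs(rng.normal(cfg.dewpoint_depression, cfg.dewpoint_spread, shape))
    td = ta - depression  # always <= ta by construction
    daylight = np.maximum(0.0, np.sin(2 * np.pi * (local_hour - 6.0) / 24.0))
    tmrt = ta + cfg.mrt_day_boost * daylight + rng.normal(0.0, cfg.mrt_noise_sd, shape)
    va = np.maximum(0.0, rng.normal(cfg.wind_mean, cfg.wind_spread, shape))

    ds = xr.Dataset(
        {
            "ta": (("time", "lat", "lon"), ta, {"units": "K"}),
            "td": (("time", "lat", "lon"), td, {"units": "K"}),
            "tmrt": (("time", "lat", "lon"), tmrt, {"units": "K"}),
            "va": (("time", "lat", "lon"), va, {"units": "m s**-1"}),
            "lsm": (("lat", "lon"), _land_fraction(cfg), {"units": "1"}),
        },
        coords={"time": time, "lat": lat, "lon": lon},
        attrs={"title": "synthetic hourly meteorological grid", "seed": cfg.seed},
    )
    return ds


def generate_station(
    cfg: SyntheticConfig,
    lat: float,
    lon: float,
    noise_sd: float = 0.0,
    gap_fraction: float = 0.0,
    grid: xr.Dataset | None = None,
) -> pd.DataFrame:
    """Station series from the nearest grid cell, with observation noise
    and missing-data gaps.

    With ``noise_sd=0`` and ``gap_fraction=0`` the series equals the grid
    cell's series exactly. Gaps drop whole timestamps. Deterministic under
    the config seed.
    """
    if grid is None:
        grid = generate_grid(cfg)
    if not (float(grid["lat"].min()) <= lat <= float(grid["lat"].max())):
        raise ValueError("station latitude outside grid")
    if not (float(grid["lon"].min()) <= lon <= float(grid["lon"].max())):
        raise ValueError("station longitude outside grid")
    cell = grid.sel(lat=lat, lon=lon, method="nearest")
    df = cell[["ta", "td", "va", "tmrt"]].to_dataframe()[["ta", "td", "va", "tmrt"]]

    rng = np.random.default_rng(cfg.seed + 1)
    if noise_sd > 0:
        for col in ("ta", "td", "tmrt"):
            df[col] = df[col] + rng.normal(0.0, noise_sd, len(df))
        df["va"] = np.maximum(0.0, df["va"] + rng.normal(0.0, noise_sd, len(df)))
    if gap_fraction > 0:
        if not (0.0 <= gap_fraction <= 1.0):
            raise ValueError("gap_fraction must lie in [0, 1]")
        n_drop = int(round(gap_fraction * len(df)))
        drop = rng.choice(len(df), size=n_drop, replace=False)
        df = df.drop(df.index[drop])
    return df
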