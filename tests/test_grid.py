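"""Grid pipeline: I/O round trips, grid/point equivalence, aggregation."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from wbgtgrid import (
    AirState,
    SyntheticConfig,
    apply_land_mask,
    compute_wbgt_grid,
    daily_max,
    generate_grid,
    monthly_mean_of_daily_max,
    read_meteo,
    wbgt_brimicombe,
    write_fields,
)
from wbgtgrid.grid import DEFAULT_VARMAP, read_station_csv


def _write_era5_style(grid: xr.Dataset, path) -> None:
    ds = grid.rename({k: v for k, v in DEFAULT_VARMAP.items() if k in grid})
    write_fields(ds, path)


class TestReadMeteo:
    def test_round_trip_shapes_and_values(self, small_grid, tmp_path):
        p = tmp_path / "in.nc"
        _write_era5_style(small_grid, p)
        back = read_meteo(p)
        for v in ("ta", "td", "va", "tmrt"):
            np.testing.assert_allclose(back[v].values, small_grid[v].values)

    def test_celsius_input_converted(self, small_grid, tmp_path):
        ds = small_grid.copy()
        ds["ta"] = (ds["ta"] - 273.15).assign_attrs(units="degC")
        p = tmp_path / "c.nc"
        _write_era5_style(ds, p)
        back = read_meteo(p)
        np.testing.assert_allclose(back["ta"].values, small_grid["ta"].values, atol=1e-10)

    def test_missing_variable_named_in_error(self, small_grid, tmp_path):
        p = tmp_path / "nomrt.nc"
        _write_era5_style(small_grid.drop_vars("tmrt"), p)
        with pytest.raises(ValueError, match="tmrt"):
            read_meteo(p)

    def test_unknown_units_rejected(self, small_grid, tmp_path):
        ds = small_grid.copy()
        ds["ta"] = ds["ta"].assign_attrs(units="furlongs")
        p = tmp_path / "bad.nc"
        _write_era5_style(ds, p)
        with pytest.raises(ValueError, match="furlongs"):
            read_meteo(p)

    def test_wind_components_combined(self, small_grid, tmp_path):
        ds = small_grid.drop_vars("va")
        rng = np.random.default_rng(0)
        u = rng.normal(0, 3, small_grid["ta"].shape)
        v = rng.normal(0, 3, small_grid["ta"].shape)
        ds["u10"] = (("time", "lat", "lon"), u)
        ds["v10"] = (("time", "lat", "lon"), v)
        p = tmp_path / "uv.nc"
        _write_era5_style(ds, p)
        back = read_meteo(p)
        np.testing.assert_allclose(back["va"].values, np.hypot(u, v), atol=1e-12)

    def test_longitude_normalized(self, small_grid, tmp_path):
        ds = small_grid.assign_coords(lon=small_grid["lon"] + 350.0)
        p = tmp_path / "lon.nc"
        _write_era5_style(ds, p)
        back = read_meteo(p)
        assert float(back["lon"].min()) >= -180.0 and float(back["lon"].max()) < 180.0

    def test_station_csv_round_trip(self, tmp_path):
        df = pd.DataFrame({
            "time": pd.date_range("2003-07-01", periods=5, freq="h"),
            "ta": 300.0, "td": 295.0, "va": 2.0, "tmrt": 310.0,
        })
        p = tmp_path / "station.csv"
        df.to_csv(p, index=False)
        back = read_station_csv(p)
        assert len(back) == 5 and list(back.columns) == ["ta", "td", "va", "tmrt"]

    def test_station_csv_missing_columns(self, tmp_path):
        p = tmp_path / "missing.csv"
        pd.DataFrame({"time": pd.date_range("2003-07-01", periods=2, freq="h"),
                      "ta": 300.0}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            read_station_csv(p)


class TestComputeWBGTGrid:
    def test_degenerate_grid_equals_point(self, small_grid):
        one = small_grid.isel(time=[0], lat=[0], lon=[0])
        res = compute_wbgt_grid(one)
        point = wbgt_brimicombe(AirState(
            ta=one["ta"].values.item(), td=one["td"].values.item(),
            va=one["va"].values.item(), tmrt=one["tmrt"].values.item(),
        ))
        assert res["wbgt"].values.item() == pytest.approx(float(point.wbgt), abs=0)

    def test_matches_scalar_loop_oracle(self, small_grid):
        sub = small_grid.isel(time=slice(0, 12))
        res = compute_wbgt_grid(sub)
        for it in range(sub.sizes["time"]):
            for ilat in range(sub.sizes["lat"]):
                for ilon in range(sub.sizes["lon"]):
                    cell = sub.isel(time=it, lat=ilat, lon=ilon)
                    point = wbgt_brimicombe(AirState(
                        ta=float(cell["ta"]), td=float(cell["td"]),
                        va=float(cell["va"]), tmrt=float(cell["tmrt"]),
                    ))
                    assert float(res["wbgt"][it, ilat, ilon]) == pytest.approx(
                        float(point.wbgt), abs=1e-9
                    )

    def test_uniform_field_gives_constant_output(self):
        ds = generate_grid(SyntheticConfig(
            seed=0, n_lat=2, n_lon=2, n_days=1, diurnal_amp=0.0,
            noise_sd=0.0, spatial_amp=0.0, dewpoint_spread=0.0,
            wind_spread=0.0, mrt_noise_sd=0.0, mrt_day_boost=0.0,
        ))
        # remove the longitude-dependent daylight term by zeroing the boost
        res = compute_wbgt_grid(ds)
        w = res["wbgt"].values
        assert np.allclose(w, w[0, 0, 0])

    def test_missing_cells_propagate(self, small_grid):
        ds = small_grid.copy(deep=True)
        ds["ta"][0, 0, 0] = np.nan
        res = compute_wbgt_grid(ds)
        assert np.isnan(res["wbgt"][0, 0, 0])
        assert np.isfinite(res["wbgt"][0, 0, 1])

    def test_method_recorded(self, small_grid):
        assert compute_wbgt_grid(small_grid, "acsm87").attrs["method"] == "acsm87"
        with pytest.raises(ValueError):
            compute_wbgt_grid(small_grid, "liljegren")


class TestAggregation:
    def test_daily_max_picks_peak_hour(self, small_grid):
        res = compute_wbgt_grid(small_grid)["wbgt"]
        dm = daily_max(res)
        assert dm.sizes["time"] == 2
        # brute force per cell over the first day
        manual = res.isel(time=slice(0, 24)).values.max(axis=0)
        np.testing.assert_allclose(dm.isel(time=0).values, manual)

    def test_daily_max_constant_field(self, small_grid):
        const = xr.full_like(small_grid["ta"], 21.5)
        dm = daily_max(const)
        assert np.allclose(dm.values, 21.5)

    def test_daily_max_shuffle_invariant(self, small_grid):
        res = compute_wbgt_grid(small_grid)["wbgt"].isel(time=slice(0, 24))
        rng = np.random.default_rng(1)
        perm = rng.permutation(24)
        shuffled = res.copy(data=res.values[perm])
        np.testing.assert_allclose(daily_max(res).values, daily_max(shuffled).values)

    def test_daily_max_skips_missing_hours(self, small_grid):
        res = compute_wbgt_grid(small_grid)["wbgt"].copy(deep=True)
        vals = res.values
        vals[0:23, 0, 0] = np.nan           # one hour left on day 1
        vals[0:24, 1, 1] = np.nan           # whole day missing
        res = res.copy(data=vals)
        dm = daily_max(res)
        assert np.isfinite(dm[0, 0, 0])
        assert np.isnan(dm[0, 1, 1])

    def test_empty_time_axis_rejected(self, small_grid):
        empty = compute_wbgt_grid(small_grid)["wbgt"].isel(time=slice(0, 0))
        with pytest.raises(ValueError):
            daily_max(empty)

    def test_monthly_mean_of_daily_max(self, small_grid):
        res = compute_wbgt_grid(small_grid)["wbgt"]
        dm = daily_max(res)
        mm = monthly_mean_of_daily_max(dm)
        np.testing.assert_allclose(mm.values, dm.values.mean(axis=0))
        one = monthly_mean_of_daily_max(dm.isel(time=[0]))
        np.testing.assert_allclose(one.values, dm.isel(time=0).values)

    def test_two_day_mean_hand_value(self, small_grid):
        a = xr.full_like(small_grid["ta"].isel(time=slice(0, 48)), 10.0)
        vals = a.values
        vals[24:] = 20.0
        a = a.copy(data=vals)
        mm = monthly_mean_of_daily_max(daily_max(a))
        assert np.allclose(mm.values, 15.0)


class TestMaskingAndWrite:
    def test_mask_extremes(self, small_grid):
        field = compute_wbgt_grid(small_grid)["wbgt"].isel(time=0)
        land = xr.ones_like(field)
        np.testing.assert_allclose(apply_land_mask(field, land).values, field.values)
        sea = xr.zeros_like(field)
        assert np.isnan(apply_land_mask(field, sea).values).all()

    def test_checkerboard_masks_half(self):
        ds = generate_grid(SyntheticConfig(seed=1, n_lat=4, n_lon=4, n_days=1,
                                           land_fraction_pattern="checkerboard"))
        field = compute_wbgt_grid(ds)["wbgt"].isel(time=0)
        masked = apply_land_mask(field, ds["lsm"])
        assert int(np.isnan(masked.values).sum()) == 8

    def test_bad_threshold_rejected(self, small_grid):
        field = compute_wbgt_grid(small_grid)["wbgt"]
        with pytest.raises(ValueError):
            apply_land_mask(field, small_grid["lsm"], threshold=1.5)

    def test_mask_commutes_with_aggregation(self, small_grid):
        field = compute_wbgt_grid(small_grid)["wbgt"]
        land = small_grid["lsm"] * 0 + np.tile([1.0, 0.0], (3, 2))
        a = monthly_mean_of_daily_max(daily_max(apply_land_mask(field, land)))
        b = apply_land_mask(monthly_mean_of_daily_max(daily_max(field)), land)
        np.testing.assert_allclose(a.values, b.values)

    def test_write_read_round_trip(self, small_grid, tmp_path):
        res = compute_wbgt_grid(small_grid)
        p = tmp_path / "out.nc"
        write_fields(res, p)
        back = xr.open_dataset(p)
        np.testing.assert_array_equal(back["wbgt"].values, res["wbgt"].values)
        assert back.attrs["method"] == "brimicombe"
        back.close()

    def test_write_encodes_missing_cells(self, small_grid, tmp_path):
        res = compute_wbgt_grid(small_grid)["wbgt"].copy(deep=True)
        vals = res.values
        vals[0, 0, 0] = np.nan
        res = res.copy(data=vals)
        p = tmp_path / "nan.nc"
        write_fields(res.to_dataset(name="wbgt"), p)
        back = xr.open_dataset(p)
        assert np.isnan(back["wbgt"].values[0, 0, 0])
        back.close()
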