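"""Deposition: annualization, nearest-neighbour regridding, cropland
scaling, constant extension."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from nbudget import deposition
from conftest import make_land_use, series_of


def monthly_grid(values_by_month, lats=(10.0,), lons=(70.0,), year=2000):
    """(time, lat, lon) grid with the given 12 per-month scalars."""
    times = pd.to_datetime([f"{year}-{m:02d}-01" for m in range(1, 13)])
    data = np.array(values_by_month, float)[:, None, None] * np.ones((12, len(lats), len(lons)))
    return xr.DataArray(data, coords={"time": times, "lat": list(lats), "lon": list(lons)},
                        dims=("time", "lat", "lon"), attrs={"units": "kg N ha-1 month-1"})


class TestAnnualize:
    @pytest.mark.parametrize(
        "months, expected",
        [
            ([1.0] * 12, 12.0),
            ([0.0] * 12, 0.0),
            ([0.1 * m for m in range(1, 13)], 7.8),
        ],
    )
    def test_annual_value_is_sum_of_months(self, months, expected):
        annual = deposition.annualize(monthly_grid(months))
        assert annual.sel(year=2000).values.item() == pytest.approx(expected, rel=1e-12)

    def test_partial_year_raises_naming_the_year(self):
        grid = monthly_grid([1.0] * 12)
        partial = grid.isel(time=slice(0, 10))
        with pytest.raises(ValueError, match="2000"):
            deposition.annualize(partial)


def annual_grid(values, lats, lons, years=(2000,)):
    data = np.broadcast_to(np.asarray(values, float), (len(years), len(lats), len(lons))).copy()
    return xr.DataArray(data, coords={"year": list(years), "lat": list(lats), "lon": list(lons)},
                        dims=("year", "lat", "lon"))


def brute_force_nearest(lat0, lon0, lats, lons):
    """Exhaustive scan oracle with the declared (lat, lon) tie-break."""
    best, best_d = None, np.inf
    for i, la in enumerate(lats):
        for j, lo in enumerate(lons):
            d = deposition._haversine_km(lat0, lon0, la, lo)
            if d < best_d:
                best, best_d = (i, j), d
    return best


class TestToDistricts:
    def test_centroid_on_cell_center_returns_that_cell(self):
        grid = annual_grid([[1.0, 2.0], [3.0, 4.0]], lats=[10, 12], lons=[70, 72])
        cent = pd.DataFrame({"district_id": ["D1"], "latitude": [12.0], "longitude": [72.0]})
        out = deposition.to_districts(grid, cent)
        assert out[("D1", 2000)] == 4.0

    def test_uniform_field_everywhere_equal(self):
        grid = annual_grid(np.full((3, 3), 5.5), lats=[10, 12, 14], lons=[70, 72, 74])
        cent = pd.DataFrame({"district_id": ["D1", "D2"], "latitude": [11.0, 13.9],
                             "longitude": [70.4, 73.0]})
        out = deposition.to_districts(grid, cent)
        assert (out == 5.5).all()

    def test_two_by_two_matches_brute_force(self):
        lats, lons = [10.0, 12.0], [70.0, 72.0]
        grid = annual_grid([[1.0, 2.0], [3.0, 4.0]], lats=lats, lons=lons)
        cent = pd.DataFrame({"district_id": ["D1"], "latitude": [10.2], "longitude": [71.8]})
        i, j = brute_force_nearest(10.2, 71.8, lats, lons)
        assert (i, j) == (0, 1)
        out = deposition.to_districts(grid, cent)
        assert out[("D1", 2000)] == grid.values[0, i, j] == 2.0

    def test_randomized_grids_agree_with_exhaustive_scan(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            nlat, nlon = rng.integers(2, 7, 2)
            lats = np.sort(rng.uniform(-60, 60, nlat))
            lons = np.sort(rng.uniform(-150, 150, nlon))
            grid = annual_grid(rng.uniform(0, 10, (nlat, nlon)), lats=lats, lons=lons)
            lat0 = rng.uniform(lats.min() - 2, lats.max() + 2)
            lon0 = rng.uniform(lons.min() - 2, lons.max() + 2)
            cent = pd.DataFrame({"district_id": ["D1"], "latitude": [lat0], "longitude": [lon0]})
            out = deposition.to_districts(grid, cent)
            i, j = brute_force_nearest(lat0, lon0, lats, lons)
            assert out[("D1", 2000)] == grid.values[0, i, j]

    def test_cutoff_raises_for_remote_centroid(self):
        grid = annual_grid([[1.0]], lats=[10.0], lons=[70.0])
        cent = pd.DataFrame({"district_id": ["D1"], "latitude": [50.0], "longitude": [120.0]})
        with pytest.raises(ValueError, match="cutoff"):
            deposition.to_districts(grid, cent, cutoff_km=100.0)


class TestCroplandDeposition:
    def test_reduces_to_raw_flux_when_cropland_equals_nca(self):
        lu = make_land_use(nca=100, gca=100, district_area=100, cropland_fraction=1.0)
        flux = series_of({("D1", 2000): 7.0})
        cs = deposition.cropland_deposition(flux, lu)
        assert cs.values[("D1", 2000)] == pytest.approx(7.0)

    def test_zero_cropland_fraction_gives_zero(self):
        lu = make_land_use(cropland_fraction=0.0)
        cs = deposition.cropland_deposition(series_of({("D1", 2000): 7.0}), lu)
        assert cs.values[("D1", 2000)] == 0.0

    def test_hand_worked_load_and_rate(self):
        lu = make_land_use(nca=100, gca=150, district_area=200, cropland_fraction=0.5)
        cs = deposition.cropland_deposition(series_of({("D1", 2000): 10.0}), lu)
        # load = 10 x 200 x 0.5 = 1000 kg over NCA 100 ha
        assert cs.values[("D1", 2000)] == pytest.approx(10.0)
        gross = deposition.cropland_deposition(series_of({("D1", 2000): 10.0}), lu, basis="gross")
        assert gross.values[("D1", 2000)] == pytest.approx(1000.0 / 150.0)


class TestExtendConstant:
    def test_carries_final_value_through_target_year(self):
        s = series_of({("D1", y): 5.0 for y in range(2010, 2014)} | {("D1", 2014): 7.3})
        out = deposition.extend_constant(s, 2017)
        for y in (2015, 2016, 2017):
            assert out[("D1", y)] == 7.3
        assert len(out) == len(s) + 3

    def test_extension_to_own_last_year_is_identity(self):
        s = series_of({("D1", 2014): 7.3})
        pd.testing.assert_series_equal(deposition.extend_constant(s, 2014), s)

    def test_backward_extension_rejected(self):
        s = series_of({("D1", 2014): 7.3})
        with pytest.raises(ValueError, match="precedes"):
            deposition.extend_constant(s, 2010)


def test_si_flux_conversion_uses_seconds_in_month():
    grid = monthly_grid([1.0e-10] * 12)
    grid.attrs["units"] = "kg m-2 s-1"
    out = deposition.si_flux_to_monthly(grid)
    jan = out.sel(time="2000-01-01").values.item()
    assert jan == pytest.approx(1.0e-10 * 31 * 86400 * 1.0e4, rel=1e-12)
    feb = out.sel(time="2000-02-01").values.item()  # 2000 is a leap year
    assert feb == pytest.approx(1.0e-10 * 29 * 86400 * 1.0e4, rel=1e-12)
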