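"""Manure pathways: excretion, census annualization, fate fractions,
gridded product."""

import numpy as np
import pandas as pd
import pytest

import nbudget as nb
from nbudget import manure as man_mod
from conftest import make_coefficients, make_land_use, make_manure_coefs


def livestock_frame(rows):
    return pd.DataFrame(rows, columns=list(nb.core.LIVESTOCK_COLUMNS))


class TestExcretionPerHead:
    @pytest.mark.parametrize(
        "n_rate, tam, expected",
        [(0.3, 500.0, 54.75), (0.3, 0.0, 0.0), (1.0, 1000.0, 365.0)],
    )
    def test_daily_rate_times_mass_times_days(self, n_rate, tam, expected):
        cf = make_coefficients(manure=make_manure_coefs([dict(category_id="cattle", n_rate=n_rate, tam=tam)]))
        assert man_mod.excretion_per_head(cf, "cattle") == pytest.approx(expected)

    def test_missing_category_policy(self):
        cf = make_coefficients()
        with pytest.warns(UserWarning):
            assert man_mod.excretion_per_head(cf, "camels") == 0.0


class TestInterpolateCensus:
    def test_linear_between_censuses(self):
        ls = livestock_frame([("D1", 1966, "cattle", 100.0), ("D1", 1971, "cattle", 200.0)])
        out = man_mod.interpolate_census(ls, range(1966, 1972))
        vals = out.set_index("year")["headcount"]
        assert vals[1968] == pytest.approx(140.0)

    def test_single_census_is_constant(self):
        ls = livestock_frame([("D1", 1966, "cattle", 50.0)])
        out = man_mod.interpolate_census(ls, range(1960, 1975))
        assert (out["headcount"] == 50.0).all()

    def test_exact_at_census_years_and_flat_outside(self):
        ls = livestock_frame([("D1", 1971, "cattle", 10.0), ("D1", 1976, "cattle", 30.0)])
        out = man_mod.interpolate_census(ls, range(1966, 1981)).set_index("year")["headcount"]
        assert out[1971] == 10.0 and out[1976] == 30.0
        assert out[1966] == 10.0 and out[1980] == 30.0  # flat extrapolation
        mids = out.loc[1971:1976]
        assert (np.diff(mids) >= 0).all() and mids.max() <= 30.0  # no overshoot

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            man_mod.interpolate_census(livestock_frame([]), range(1966, 1970))


class TestDistrictExcretion:
    def test_hand_worked_density_product(self):
        hc = pd.DataFrame({"district_id": ["D1"], "category_id": ["cattle"],
                           "year": [2000], "headcount": [200.0]})
        out = man_mod.district_excretion(hc, {"cattle": 54.75}, make_land_use(nca=100), "net")
        assert out["n_excreted_per_ha"].iloc[0] == pytest.approx(109.5)

    def test_zero_headcount_gives_zero(self):
        hc = pd.DataFrame({"district_id": ["D1"], "category_id": ["cattle"],
                           "year": [2000], "headcount": [0.0]})
        out = man_mod.district_excretion(hc, {"cattle": 54.75}, make_land_use(), "net")
        assert out["n_excreted_per_ha"].iloc[0] == 0.0

    def test_doubling_area_halves_per_ha_series(self):
        hc = pd.DataFrame({"district_id": ["D1"], "category_id": ["cattle"],
                           "year": [2000], "headcount": [200.0]})
        small = man_mod.district_excretion(hc, {"cattle": 50.0}, make_land_use(nca=100), "net")
        big = man_mod.district_excretion(hc, {"cattle": 50.0}, make_land_use(nca=200, gca=250), "net")
        assert big["n_excreted_per_ha"].iloc[0] == pytest.approx(small["n_excreted_per_ha"].iloc[0] / 2)


class TestAppliedFractions:
    def test_hand_worked_global_fraction(self):
        cf = make_coefficients(manure=make_manure_coefs([dict(
            category_id="cattle",
            f_mt_irrigated=0.5, f_mo_irrigated=0.1, f_loss_irrigated=0.3,
            f_mt_rainfed=0.5, f_mo_rainfed=0.1, f_loss_rainfed=0.3)]))
        assert man_mod.applied_fraction_global(cf, "cattle") == pytest.approx(0.315)

    def test_unmanaged_manure_contributes_nothing(self):
        cf = make_coefficients(manure=make_manure_coefs([dict(
            category_id="cattle", f_mt_irrigated=0.0, f_mt_rainfed=0.0)]))
        assert man_mod.applied_fraction_global(cf, "cattle") == 0.0

    def test_lossless_case_returns_f_mt(self):
        cf = make_coefficients(manure=make_manure_coefs([dict(
            category_id="cattle",
            f_mt_irrigated=0.5, f_mo_irrigated=0.0, f_loss_irrigated=0.0,
            f_mt_rainfed=0.5, f_mo_rainfed=0.0, f_loss_rainfed=0.0)]))
        assert man_mod.applied_fraction_global(cf, "cattle") == pytest.approx(0.5)

    def test_shares_must_sum_to_one(self):
        cf = make_coefficients()
        with pytest.raises(ValueError, match="sum"):
            man_mod.applied_fraction_global(cf, "cattle", {"irrigated": 0.7, "rainfed": 0.7})


def excretion_frame(rows):
    return pd.DataFrame(rows, columns=["district_id", "category_id", "year", "n_excreted_per_ha"])


class TestManureApplied:
    def test_india_fraction_hand_worked(self):
        cf = make_coefficients(manure=make_manure_coefs([dict(
            category_id="cattle", am_cn=0.2, am_cl=0.1, am_fl=0.25)]))
        ex = excretion_frame([("D1", "cattle", 2000, 100.0)])
        cs = man_mod.manure_applied(ex, cf, "CENSUS_INDIA", make_land_use(), "net")
        assert cs.values[("D1", 2000)] == pytest.approx(45.0)

    def test_identity_bound_when_all_manure_reaches_cropland(self):
        cf = make_coefficients(manure=make_manure_coefs([dict(
            category_id="cattle",
            f_mt_irrigated=1.0, f_mo_irrigated=0.0, f_loss_irrigated=0.0,
            f_mt_rainfed=1.0, f_mo_rainfed=0.0, f_loss_rainfed=0.0)]))
        ex = excretion_frame([("D1", "cattle", 2000, 80.0)])
        cs = man_mod.manure_applied(ex, cf, "CENSUS_GLOBAL", make_land_use(), "net")
        assert cs.values[("D1", 2000)] == pytest.approx(80.0)

    def test_multi_category_sum_matches_per_category_recomputation(self):
        rows = [dict(category_id=c) for c in ("cattle", "buffalo", "goats")]
        cf = make_coefficients(manure=make_manure_coefs(rows))
        ex = excretion_frame([("D1", "cattle", 2000, 50.0), ("D1", "buffalo", 2000, 30.0),
                              ("D1", "goats", 2000, 20.0)])
        cs = man_mod.manure_applied(ex, cf, "CENSUS_GLOBAL", make_land_use(), "net")
        expected = sum(v * man_mod.applied_fraction_global(cf, c)
                       for c, v in [("cattle", 50.0), ("buffalo", 30.0), ("goats", 20.0)])
        assert cs.values[("D1", 2000)] == pytest.approx(expected, rel=1e-12)

    def test_india_method_ignores_non_ruminants(self):
        rows = [dict(category_id=c) for c in ("cattle", "poultry")]
        cf = make_coefficients(manure=make_manure_coefs(rows))
        ex = excretion_frame([("D1", "cattle", 2000, 100.0), ("D1", "poultry", 2000, 100.0)])
        cs = man_mod.manure_applied(ex, cf, "CENSUS_INDIA", make_land_use(), "net")
        assert cs.values[("D1", 2000)] == pytest.approx(45.0)  # cattle only

    def test_applied_never_exceeds_excreted(self, tiny_bundle):
        lu = tiny_bundle.land_use
        cf = tiny_bundle.coefficients
        years = sorted(lu["year"].unique())
        hc = man_mod.interpolate_census(tiny_bundle.livestock, years)
        per_head = {c: man_mod.excretion_per_head(cf, c) for c in hc["category_id"].unique()}
        ex = man_mod.district_excretion(hc, per_head, lu, "net")
        total_ex = ex.groupby(["district_id", "year"])["n_excreted_per_ha"].sum()
        for method in ("CENSUS_GLOBAL", "CENSUS_INDIA"):
            cs = man_mod.manure_applied(ex, cf, method, lu, "net")
            assert (cs.values >= 0).all()
            assert (cs.values <= total_ex.reindex(cs.values.index) + 1e-9).all()

    def test_methods_coincide_when_fractions_engineered_equal(self):
        # 1 - (am_cn+am_cl+am_fl) = 0.45 and F_M = 0.5 x (1-0.1) x (1-0) = 0.45
        cf = make_coefficients(manure=make_manure_coefs([dict(
            category_id="cattle",
            f_mt_irrigated=0.5, f_mo_irrigated=0.1, f_loss_irrigated=0.0,
            f_mt_rainfed=0.5, f_mo_rainfed=0.1, f_loss_rainfed=0.0,
            am_cn=0.2, am_cl=0.1, am_fl=0.25)]))
        ex = excretion_frame([("D1", "cattle", 2000, 100.0)])
        g = man_mod.manure_applied(ex, cf, "CENSUS_GLOBAL", make_land_use(), "net").values
        i = man_mod.manure_applied(ex, cf, "CENSUS_INDIA", make_land_use(), "net").values
        np.testing.assert_allclose(g.to_numpy(), i.to_numpy(), rtol=1e-12)

    def test_unknown_method_rejected(self):
        cf = make_coefficients()
        with pytest.raises(ValueError, match="method"):
            man_mod.manure_applied(excretion_frame([]), cf, "IPCC", make_land_use(), "net")


class TestGriddedProduct:
    def test_uniform_grid_reaches_every_district(self, tiny_bundle):
        import xarray as xr

        grid = xr.full_like(tiny_bundle.manure_grid, 30.0)
        grid.attrs = dict(tiny_bundle.manure_grid.attrs)
        cs = man_mod.manure_from_grid(grid, tiny_bundle.centroids, tiny_bundle.land_use, "net")
        assert np.allclose(cs.values.to_numpy(), 30.0)

    def test_constant_extension_past_grid_end(self, tiny_bundle):
        import xarray as xr

        grid = tiny_bundle.manure_grid.sel(year=slice(1966, 1970)) * 0 + 12.5
        grid.attrs = dict(tiny_bundle.manure_grid.attrs)
        cs = man_mod.manure_from_grid(grid, tiny_bundle.centroids, tiny_bundle.land_use, "net",
                                      through_year=1975)
        for y in (1971, 1973, 1975):
            sub = cs.values.xs(y, level="year")
            assert np.allclose(sub.to_numpy(), 12.5)

    def test_coverage_gap_before_panel_start_rejected(self, tiny_bundle):
        grid = tiny_bundle.manure_grid.sel(year=slice(1970, 2014))
        with pytest.raises(ValueError, match="starts"):
            man_mod.manure_from_grid(grid, tiny_bundle.centroids, tiny_bundle.land_use, "net")

    def test_matches_brute_force_nearest_cell(self, tiny_bundle):
        from test_deposition import brute_force_nearest

        grid = tiny_bundle.manure_grid
        cs = man_mod.manure_from_grid(grid, tiny_bundle.centroids, tiny_bundle.land_use, "net")
        lats, lons = grid["lat"].values, grid["lon"].values
        years = [int(y) for y in grid["year"].values]
        for r in tiny_bundle.centroids.itertuples():
            i, j = brute_force_nearest(r.latitude, r.longitude, lats, lons)
            y = years[0]
            assert cs.values[(r.district_id, y)] == pytest.approx(float(grid.values[0, i, j]))
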