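"""Manure N applied to cropland: three alternative estimates.

1. CENSUS_GLOBAL — livestock-census excretion routed through global manure
   fate fractions: per-head excretion (excretion rate x typical animal mass
   / 1000 x 365 days), times livestock density, times
   F_MT x (1 - F_MO) x (1 - F_Loss) averaged over production systems
   (irrigated / rainfed), summed over all categories.
2. CENSUS_INDIA — the same excretion, restricted to the ruminant categories
   (cattle, buffalo, goats, sheep), times the India-specific applied share
   1 - (AM_CN + AM_CL + AM_FL) (collection loss, construction use, fuel).
3. GRIDDED — an external gridded manure-application product sampled at
   district centroids by nearest-neighbour and carried forward at a
   constant rate past the product's final year.

Quinquennial censuses are annualized by linear interpolation between
censuses with flat extrapolation outside the census range.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from . import core, deposition
from .core import ComponentSeries, NET


def excretion_per_head(coefficients: core.CoefficientSet, category: str) -> float:
    """Annual N excretion, kg N animal-1 yr-1: n_rate x (TAM/1000) x 365."""
    rec = coefficients.manure_registry().lookup(category)
    if rec is None:
        return 0.0
    return float(rec["n_rate"]) * float(rec["tam"]) / 1000.0 * 365.0


def interpolate_census(livestock: pd.DataFrame, years: list[int] | range) -> pd.DataFrame:
    """Annual headcounts from quinquennial censuses.

    Linear interpolation between census years, constant extrapolation
    before the first and after the last census; exact at census years.
    Returns columns (district_id, category_id, year, headcount).
    """
    if livestock.empty:
        raise ValueError("empty livestock table")
    years = np.asarray(sorted(years))
    out = []
    for (district, category), grp in livestock.groupby(["district_id", "category_id"]):
        grp = grp.sort_values("census_year")
        # np.interp clamps outside the census range (flat extrapolation)
        interp = np.interp(years, grp["census_year"].to_numpy(float), grp["headcount"].to_numpy(float))
        out.append(pd.DataFrame({"district_id": district, "category_id": category, "year": years, "headcount": interp}))
    return pd.concat(out, ignore_index=True)


def district_excretion(
    headcounts: pd.DataFrame,
    per_head: dict[str, float],
    land_use: pd.DataFrame,
    basis: str = NET,
    *,
    policy: str = "skip",
) -> pd.DataFrame:
    """Per-ha excretion by category: N_ex(j) x density(i, j, y).

    Density is headcount / area(basis), head ha-1.  Returns columns
    (district_id, category_id, year, n_excreted_per_ha).
    """
    core.check_basis(basis)
    area = core.basis_area(land_use, basis)
    hc = headcounts.merge(area.rename("area").reset_index(), on=["district_id", "year"], how="left")
    bad = (hc["area"] == 0) & (hc["headcount"] > 0)
    if bad.any():
        msg = f"{int(bad.sum())} records with zero {basis} area but nonzero headcount"
        if policy == "error":
            raise ValueError(msg)
        import warnings

        warnings.warn(msg + "; flagged missing (dropped)", stacklevel=2)
        hc = hc[~bad]
    hc["n_excreted_per_ha"] = np.where(
        hc["headcount"] > 0,
        hc["category_id"].map(per_head).fillna(0.0) * hc["headcount"] / hc["area"],
        0.0,
    )
    return hc[["district_id", "category_id", "year", "n_excreted_per_ha"]]


def applied_fraction_global(
    coefficients: core.CoefficientSet,
    category: str,
    prosys_shares: dict[str, float] | None = None,
) -> float:
    """Cropland-applied share of excreted N under the global pathway.

    F_M = sum over production systems of
    share x F_MT x (1 - F_MO) x (1 - F_Loss); lies in [0, 1].
    """
    shares = dict(prosys_shares if prosys_shares is not None else coefficients.prosys_shares)
    if abs(sum(shares.values()) - 1.0) > 1e-9:
        raise ValueError(f"production-system shares sum to {sum(shares.values())}, not 1")
    rec = coefficients.manure_registry().lookup(category)
    if rec is None:
        return 0.0
    total = 0.0
    for prosys, share in shares.items():
        if prosys not in core.PRODUCTION_SYSTEMS:
            raise ValueError(f"unknown production system {prosys!r}")
        total += share * rec[f"f_mt_{prosys}"] * (1 - rec[f"f_mo_{prosys}"]) * (1 - rec[f"f_loss_{prosys}"])
    return float(total)


def applied_fraction_india(coefficients: core.CoefficientSet, category: str) -> float:
    """India-specific applied share: 1 - (AM_CN + AM_CL + AM_FL)."""
    rec = coefficients.manure_registry().lookup(category)
    if rec is None:
        return 0.0
    return float(1.0 - (rec["am_cn"] + rec["am_cl"] + rec["am_fl"]))


def manure_applied(
    excretion: pd.DataFrame,
    coefficients: core.CoefficientSet,
    method: str,
    land_use: pd.DataFrame,
    basis: str = NET,
) -> ComponentSeries:
    """Census-based MAN component from a per-category excretion table.

    CENSUS_GLOBAL sums all categories weighted by the global fate
    fractions; CENSUS_INDIA sums only the ruminant categories weighted by
    the India applied share.  Either way applied <= excreted over the
    included categories.
    """
    if method == "CENSUS_GLOBAL":
        cats = excretion["category_id"].unique()
        frac = {c: applied_fraction_global(coefficients, c) for c in cats}
        sub = excretion
    elif method == "CENSUS_INDIA":
        sub = excretion[excretion["category_id"].isin(core.RUMINANT_CATEGORIES)]
        frac = {c: applied_fraction_india(coefficients, c) for c in sub["category_id"].unique()}
    else:
        raise ValueError(f"method must be CENSUS_GLOBAL or CENSUS_INDIA, not {method!r}")
    applied = sub["n_excreted_per_ha"] * sub["category_id"].map(frac)
    rate = applied.groupby([sub["district_id"], sub["year"]]).sum()
    rate = rate.reindex(core.basis_area(land_use, basis).index, fill_value=0.0)
    tag = "man-census-global" if method == "CENSUS_GLOBAL" else "man-census-india"
    return ComponentSeries("MAN", f"{tag}_{basis}", basis, rate)


def manure_census(
    livestock: pd.DataFrame,
    coefficients: core.CoefficientSet,
    land_use: pd.DataFrame,
    method: str,
    basis: str = NET,
) -> ComponentSeries:
    """Convenience wrapper: census table -> annualized -> MAN component."""
    years = sorted(land_use["year"].unique())
    cats = coefficients.manure_registry().resolve(livestock["category_id"].unique())
    hc = interpolate_census(livestock[livestock["category_id"].isin(cats)], years)
    per_head = {c: excretion_per_head(coefficients, c) for c in cats}
    excretion = district_excretion(hc, per_head, land_use, basis)
    return manure_applied(excretion, coefficients, method, land_use, basis)


def manure_from_grid(
    grid: xr.DataArray,
    centroids: pd.DataFrame,
    land_use: pd.DataFrame,
    basis: str = NET,
    *,
    through_year: int | None = None,
    cutoff_km: float | None = None,
) -> ComponentSeries:
    """MAN component from a gridded application-rate product.

    The grid (year, lat, lon; kg N ha-1 yr-1 of NCA) is sampled at district
    centroids by the same nearest-neighbour rule as deposition, then held
    constant from its final year through ``through_year``.  Rates convert
    to the gross basis through the load (rate x NCA / GCA).
    """
    core.check_basis(basis)
    panel_years = sorted(land_use["year"].unique())
    grid_start = int(grid["year"].min())
    if grid_start > panel_years[0]:
        raise ValueError(f"gridded manure product starts {grid_start}, after panel start {panel_years[0]}")
    sampled = deposition.to_districts(grid, centroids, cutoff_km=cutoff_km)
    through = int(through_year if through_year is not None else panel_years[-1])
    if through > int(sampled.index.get_level_values("year").max()):
        sampled = deposition.extend_constant(sampled, through)
    lu = land_use.set_index(["district_id", "year"]).sort_index()
    sampled = sampled.reindex(lu.index).dropna()
    load = sampled * lu["net_cropped_area"].reindex(sampled.index)
    area = core.basis_area(land_use, basis).reindex(sampled.index)
    rate = (load / area.where(area > 0, other=np.nan)).fillna(0.0)
    return ComponentSeries("MAN", f"man-gridded_{basis}", basis, rate)
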