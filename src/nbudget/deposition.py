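"""Atmospheric N deposition: monthly grid -> annual per-district cropland flux.

The pipeline takes a gridded monthly total-N deposition field (oxidized +
reduced, wet + dry), sums it to annual values, samples it at district
centroids by nearest-neighbour (great-circle distance), and scales the
sampled flux by each district's cropland area to obtain the DEP component in
kg N ha-1 yr-1 of the chosen cropped-area basis.

The grid carries kg N ha-1 month-1 internally; :func:`si_flux_to_monthly`
converts fields shipped as SI fluxes (kg m-2 s-1) at the boundary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from . import core
from .core import ComponentSeries, NET

EARTH_RADIUS_KM = 6371.0088


def si_flux_to_monthly(grid: xr.DataArray) -> xr.DataArray:
    """Convert an SI deposition flux (kg m-2 s-1) to kg N ha-1 month-1.

    Multiplies each time slice by the number of seconds in its calendar
    month and by 1e4 m2 per ha.
    """
    t = pd.DatetimeIndex(grid["time"].values)
    seconds = xr.DataArray(t.days_in_month.to_numpy() * 86400.0, coords={"time": grid["time"]}, dims="time")
    out = grid * seconds * 1.0e4
    out.attrs = dict(grid.attrs, units="kg N ha-1 month-1")
    return out


def annualize(grid: xr.DataArray) -> xr.DataArray:
    """Sum complete 12-month years to an annual grid (kg N ha-1 yr-1).

    Raises ``ValueError`` naming the first year with partial coverage.
    """
    years = pd.DatetimeIndex(grid["time"].values).year
    counts = pd.Series(years).value_counts()
    partial = sorted(counts[counts != 12].index.tolist())
    if partial:
        raise ValueError(f"partial monthly coverage for year {partial[0]} ({int(counts[partial[0]])} months)")
    annual = grid.groupby(xr.DataArray(years, coords={"time": grid["time"]}, dims="time", name="year")).sum("time")
    annual.attrs = dict(grid.attrs, units="kg N ha-1 yr-1")
    return annual.transpose("year", "lat", "lon")


def _haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km; arguments in degrees, broadcastable."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = np.sin((lat2 - lat1) / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def nearest_cell_indices(
    centroids: pd.DataFrame,
    lats: np.ndarray,
    lons: np.ndarray,
    *,
    cutoff_km: float | None = None,
) -> pd.DataFrame:
    """(lat_idx, lon_idx) of the nearest grid-cell centre per district.

    Distance is great-circle; ties break to the lowest latitude index, then
    the lowest longitude index.  A centroid farther than ``cutoff_km`` from
    every cell centre raises ``ValueError``.
    """
    lat_g, lon_g = np.meshgrid(np.asarray(lats, float), np.asarray(lons, float), indexing="ij")
    rows = []
    for _, r in centroids.iterrows():
        if not (-90 <= r.latitude <= 90) or not (-180 <= r.longitude < 360):
            raise ValueError(f"district {r.district_id}: centroid ({r.latitude}, {r.longitude}) out of range")
        d = _haversine_km(r.latitude, r.longitude, lat_g, lon_g)
        # C-order argmin returns the first minimum: lowest lat index, then lon
        flat = int(np.argmin(d))
        i, j = np.unravel_index(flat, d.shape)
        if cutoff_km is not None and d[i, j] > cutoff_km:
            raise ValueError(
                f"district {r.district_id}: nearest cell {d[i, j]:.1f} km away exceeds cutoff {cutoff_km} km"
            )
        rows.append((r.district_id, int(i), int(j), float(d[i, j])))
    return pd.DataFrame(rows, columns=["district_id", "lat_idx", "lon_idx", "distance_km"]).set_index("district_id")


def to_districts(
    annual: xr.DataArray,
    centroids: pd.DataFrame,
    *,
    cutoff_km: float | None = None,
) -> pd.Series:
    """Nearest-neighbour sample of an annual (year, lat, lon) grid.

    Returns a Series of kg N ha-1 yr-1 indexed by (district_id, year).
    """
    idx = nearest_cell_indices(centroids, annual["lat"].values, annual["lon"].values, cutoff_km=cutoff_km)
    years = [int(y) for y in annual["year"].values]
    data = annual.values  # (year, lat, lon)
    frames = {}
    for district_id, r in idx.iterrows():
        frames[district_id] = data[:, int(r.lat_idx), int(r.lon_idx)]
    out = pd.DataFrame(frames, index=pd.Index(years, name="year")).T.stack()
    out.index.set_names(["district_id", "year"], inplace=True)
    out.name = "flux"
    return out.sort_index()


def extend_constant(series: pd.Series, through_year: int) -> pd.Series:
    """Carry each district's last-year value forward through ``through_year``.

    Mirrors the constant-rate rule used to fill 2015-2017 when a gridded
    product ends in 2014.  Extending to (or before) the series' own last
    year returns it unchanged; ``through_year`` below the last year is an
    error.
    """
    last = int(series.index.get_level_values("year").max())
    if through_year < last:
        raise ValueError(f"through_year {through_year} precedes series end {last}")
    if through_year == last:
        return series
    tail = series.xs(last, level="year")
    pieces = [series]
    for y in range(last + 1, through_year + 1):
        ext = tail.copy()
        ext.index = pd.MultiIndex.from_product([tail.index, [y]], names=["district_id", "year"])
        pieces.append(ext)
    out = pd.concat(pieces).sort_index()
    out.name = series.name
    return out


def cropland_deposition(
    district_flux: pd.Series,
    land_use: pd.DataFrame,
    *,
    basis: str = NET,
    policy: str = "skip",
) -> ComponentSeries:
    """Scale a per-district flux by cropland area into the DEP component.

    District-total cropland load = flux x district_area x cropland_fraction;
    the stored rate is load / area(basis).  When the cropland area equals
    the basis area this reduces to the raw flux.
    """
    lu = land_use.set_index(["district_id", "year"]).sort_index()
    flux, lu = district_flux.align(lu, join="inner", axis=0)
    load = flux * lu["district_area"] * lu["cropland_fraction"]
    area = lu["net_cropped_area"] if basis == NET else lu["gross_cropped_area"]
    core.check_basis(basis)
    bad = (area == 0) & (load > 0)
    if bad.any():
        msg = f"{int(bad.sum())} district-years with zero {basis} area but nonzero deposition load"
        if policy == "error":
            raise ValueError(msg)
        import warnings

        warnings.warn(msg + "; flagged missing (dropped)", stacklevel=2)
    rate = (load / area).where(load > 0, 0.0)[~bad]
    return ComponentSeries("DEP", f"dep-nn_{basis}", basis, rate)
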