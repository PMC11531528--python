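"""Synthetic input bundles with known ground truth.

Generates internally consistent district-year panels (land use, fertilizer,
crop area/production, quinquennial livestock censuses), gridded monthly
deposition and annual manure-application fields, coefficient tables and a
district -> region mapping, so that every pipeline stage is testable with
no external downloads.

The default scenario emulates the shape of a half-century Indian district
panel: fertilizer application follows a logistic trajectory (slow start,
rapid rise, plateau) from a few kg N ha-1 in the mid-1960s towards
>100 kg N ha-1, yields grow steadily, livestock counts are reported only
every five years, the deposition grid is coarse (1.9 x 2.5 degrees,
monthly, ending 2014) and the manure grid finer (1.0 degree, annual,
ending 2014).  Magnitudes are order-of-magnitude plausible, nothing more.

:func:`ground_truth_surplus` recomputes any ensemble member's surplus by
direct straight-line arithmetic over the bundle tables, sharing no code
with the pipeline modules; it is the oracle for end-to-end recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from . import core
from .core import CoefficientSet, ComponentSeries, EnsembleMember, InputBundle

# ---------------------------------------------------------------------------
# default coefficient tables (documented placeholders of literature-plausible
# magnitude; real analyses should supply their own tables)

_CROP_MASTER = pd.DataFrame(
    # crop, base yield (kg/ha), area weight, N content FAO / BOUWMAN (kg N per
    # kg product), %Ndfa, NHI, BGN, area-based fixation rate (kg N/ha/yr)
    [
        ("rice",      1800, 30, 0.0136, 0.0125, 0.0,  0.0,  1.0, 0.0),
        ("wheat",     1500, 25, 0.0209, 0.0190, 0.0,  0.0,  1.0, 0.0),
        ("maize",     1200, 10, 0.0145, 0.0135, 0.0,  0.0,  1.0, 0.0),
        ("sorghum",    900, 10, 0.0150, 0.0140, 0.0,  0.0,  1.0, 0.0),
        ("chickpea",   800,  8, 0.0330, 0.0300, 0.65, 0.75, 1.6, 22.0),
        ("pigeonpea",  700,  6, 0.0320, 0.0310, 0.70, 0.65, 1.8, 25.0),
        ("groundnut", 1000,  6, 0.0280, 0.0260, 0.60, 0.80, 1.5, 30.0),
        ("sugarcane", 40000, 5, 0.0014, 0.0012, 0.0,  0.0,  1.0, 0.0),
    ],
    columns=["crop_id", "base_yield", "area_weight", "nc_fao", "nc_bouwman",
             "pct_ndfa", "nhi", "bgn", "area_rate"],
)

_MANURE_MASTER = pd.DataFrame(
    # category, excretion rate (kg N / 1000 kg mass / day), typical animal
    # mass (kg/head), managed fraction per system, other-use fraction,
    # volatilization loss, India fractions (collection loss, construction,
    # burnt as fuel), base density (head per ha NCA)
    [
        ("cattle",   0.34, 275.0, 0.55, 0.45, 0.10, 0.05, 0.25, 0.20, 0.10, 0.05, 0.30, 0.50),
        ("buffalo",  0.32, 380.0, 0.55, 0.45, 0.10, 0.05, 0.25, 0.20, 0.10, 0.05, 0.30, 0.30),
        ("poultry",  0.82,   1.8, 0.60, 0.50, 0.10, 0.05, 0.25, 0.20, 0.00, 0.00, 0.00, 2.00),
        ("chickens", 0.82,   0.9, 0.60, 0.50, 0.10, 0.05, 0.25, 0.20, 0.00, 0.00, 0.00, 3.00),
        ("pigs",     0.50,  50.0, 0.70, 0.60, 0.10, 0.05, 0.25, 0.20, 0.00, 0.00, 0.00, 0.10),
        ("goats",    1.37,  30.0, 0.35, 0.30, 0.10, 0.05, 0.25, 0.20, 0.10, 0.05, 0.05, 0.80),
        ("sheep",    1.17,  28.0, 0.35, 0.30, 0.10, 0.05, 0.25, 0.20, 0.10, 0.05, 0.05, 0.60),
    ],
    columns=["category_id", "n_rate", "tam",
             "f_mt_irrigated", "f_mt_rainfed", "f_mo_irrigated", "f_mo_rainfed",
             "f_loss_irrigated", "f_loss_rainfed", "am_cn", "am_cl", "am_fl",
             "base_density"],
)


def default_coefficients(crop_ids=None, categories=None, *, policy: str = "skip") -> CoefficientSet:
    """The bundled placeholder coefficient set, optionally subset."""
    cm = _CROP_MASTER if crop_ids is None else _CROP_MASTER[_CROP_MASTER["crop_id"].isin(crop_ids)]
    mm = _MANURE_MASTER if categories is None else _MANURE_MASTER[_MANURE_MASTER["category_id"].isin(categories)]
    bnf = cm[["crop_id", "pct_ndfa", "nhi", "bgn", "area_rate"]].copy()
    n_content = pd.concat(
        [
            cm[["crop_id", "nc_fao"]].rename(columns={"nc_fao": "n_content"}).assign(source="FAO"),
            cm[["crop_id", "nc_bouwman"]].rename(columns={"nc_bouwman": "n_content"}).assign(source="BOUWMAN"),
        ],
        ignore_index=True,
    )[["crop_id", "source", "n_content"]]
    man = mm.drop(columns="base_density")
    return CoefficientSet(bnf=bnf, n_content=n_content, manure=man, policy=policy)


# ---------------------------------------------------------------------------
# scenario configuration


@dataclass
class ScenarioConfig:
    """Knobs of the synthetic study conditions (units noted per field)."""

    n_districts: int = 25
    n_states: int = 5
    start_year: int = 1966
    end_year: int = 2017
    n_crops: int = 8
    livestock_categories: tuple = core.LIVESTOCK_CATEGORIES
    # fertilizer application rate trajectory, kg N ha-1 (NCA) yr-1, logistic
    fert_floor: float = 2.0
    fert_ceiling: float = 130.0
    fert_midpoint_year: float = 1995.0
    fert_steepness: float = 0.10  # yr-1
    # multiplicative yield growth from start to end year (linear in time)
    yield_start_factor: float = 0.55
    yield_end_factor: float = 2.2
    # livestock fractional growth per year
    livestock_growth: float = 0.015
    # deposition field, kg N ha-1 yr-1: base + N-S gradient + linear trend
    dep_base: float = 5.0
    dep_gradient: float = 2.0
    dep_trend: float = 0.05  # per year
    dep_start_year: int = 1966
    dep_end_year: int = 2014
    # gridded manure-application product, kg N ha-1 (NCA) yr-1
    manure_grid_base: float = 12.0
    manure_grid_gradient: float = 4.0
    manure_grid_trend: float = 0.08
    manure_grid_end_year: int = 2014
    # multiplicative log-normal noise sigmas (0 => exactly on trend)
    noise_fert: float = 0.05
    noise_yield: float = 0.08
    noise_livestock: float = 0.05
    rng_seed: int = 0

    def validate(self) -> None:
        if self.end_year < self.start_year:
            raise ValueError("end_year must be >= start_year (degenerate span)")
        for name in ("n_districts", "n_states", "n_crops"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not self.livestock_categories:
            raise ValueError("need at least one livestock category")
        for name in ("noise_fert", "noise_yield", "noise_livestock"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_crops > len(_CROP_MASTER):
            raise ValueError(f"at most {len(_CROP_MASTER)} crops available")
        if not self.dep_start_year <= self.dep_end_year:
            raise ValueError("deposition span is empty")

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.end_year + 1))

    @property
    def census_years(self) -> list[int]:
        return list(range(self.start_year, self.end_year + 1, core.CENSUS_INTERVAL))


def logistic_curve(year, floor: float, ceiling: float, midpoint: float, steepness: float):
    """floor + (ceiling - floor) / (1 + exp(-steepness (year - midpoint)))."""
    year = np.asarray(year, dtype=float)
    return floor + (ceiling - floor) / (1.0 + np.exp(-steepness * (year - midpoint)))


# ---------------------------------------------------------------------------
# generator

#: monthly weights used to disaggregate annual deposition; sum to 1 (monsoon
#: peak in July)
_MONTH_WEIGHTS = np.array([1 + 0.5 * math.sin(2 * math.pi * (m - 4) / 12) for m in range(1, 13)])
_MONTH_WEIGHTS = _MONTH_WEIGHTS / _MONTH_WEIGHTS.sum()

_LAT_SPAN = (8.0, 34.0)
_LON_SPAN = (68.0, 92.0)


def _noise(rng: np.random.Generator, sigma: float, size) -> np.ndarray:
    if sigma == 0:
        return np.ones(size)
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def generate_bundle(config: ScenarioConfig | None = None) -> InputBundle:
    """One complete, internally consistent input bundle.

    Deterministic given ``config.rng_seed``: the same config yields an
    identical bundle on every call.
    """
    config = config or ScenarioConfig()
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    years = config.years
    districts = [f"D{i + 1:03d}" for i in range(config.n_districts)]
    crops_used = _CROP_MASTER.head(config.n_crops)

    # --- land use: constant per district, cropland area == NCA exactly
    nca = rng.uniform(5.0e4, 3.0e5, config.n_districts)
    intensity = rng.uniform(1.1, 1.8, config.n_districts)  # GCA/NCA in [1, 2]
    cropfrac = rng.uniform(0.35, 0.7, config.n_districts)
    land_use = pd.DataFrame(
        [
            (d, y, nca[i], nca[i] * intensity[i], nca[i] / cropfrac[i], cropfrac[i])
            for i, d in enumerate(districts)
            for y in years
        ],
        columns=list(core.LAND_USE_COLUMNS),
    )

    # --- centroids and region mapping
    lat = rng.uniform(10.0, 30.0, config.n_districts)
    lon = rng.uniform(70.0, 88.0, config.n_districts)
    centroids = pd.DataFrame({"district_id": districts, "latitude": lat, "longitude": lon})
    rows = []
    for i, d in enumerate(districts):
        rows.append((d, "state", f"S{i % config.n_states + 1:02d}"))
        basin = f"B{min(2, int((lon[i] - 68.0) // 8.0)) + 1}"
        rows.append((d, "basin", basin))
        rows.append((d, "subbasin", f"{basin}-{1 if lat[i] < 20.0 else 2}"))
        rows.append((d, "national", "ALL"))
    region_mapping = pd.DataFrame(rows, columns=list(core.MAPPING_COLUMNS))

    # --- fertilizer: logistic rate x district factor x noise, as a load
    fert_factor = rng.lognormal(0.0, 0.2, config.n_districts)
    curve = logistic_curve(years, config.fert_floor, config.fert_ceiling,
                           config.fert_midpoint_year, config.fert_steepness)
    fert_noise = _noise(rng, config.noise_fert, (config.n_districts, len(years)))
    fertilizer = pd.DataFrame(
        [
            (d, y, curve[t] * fert_factor[i] * nca[i] * fert_noise[i, t])
            for i, d in enumerate(districts)
            for t, y in enumerate(years)
        ],
        columns=list(core.FERTILIZER_COLUMNS),
    )

    # --- crops: fixed district area shares of GCA, growing yields
    shares = rng.dirichlet(crops_used["area_weight"].to_numpy(float), size=config.n_districts)
    yfac = rng.lognormal(0.0, 0.15, config.n_districts)
    span = max(config.end_year - config.start_year, 1)
    growth = np.array(
        [config.yield_start_factor + (config.yield_end_factor - config.yield_start_factor) * (y - config.start_year) / span
         for y in years]
    )
    yield_noise = _noise(rng, config.noise_yield, (config.n_districts, len(years), config.n_crops))
    crop_rows = []
    for i, d in enumerate(districts):
        gca = nca[i] * intensity[i]
        for t, y in enumerate(years):
            for c, crop in enumerate(crops_used.itertuples()):
                area = shares[i, c] * gca
                yld = crop.base_yield * growth[t] * yfac[i] * yield_noise[i, t, c]
                crop_rows.append((d, y, crop.crop_id, area, area * yld))
    crops = pd.DataFrame(crop_rows, columns=list(core.CROP_COLUMNS))

    # --- livestock: only at quinquennial census years
    categories = list(config.livestock_categories)
    base_density = _MANURE_MASTER.set_index("category_id")["base_density"]
    dfac = rng.lognormal(0.0, 0.3, (config.n_districts, len(categories)))
    census_years = config.census_years
    ls_noise = _noise(rng, config.noise_livestock, (config.n_districts, len(census_years), len(categories)))
    ls_rows = []
    for i, d in enumerate(districts):
        for t, cy in enumerate(census_years):
            for j, cat in enumerate(categories):
                head = (
                    base_density.get(cat, 0.2) * nca[i] * dfac[i, j]
                    * (1.0 + config.livestock_growth) ** (cy - config.start_year)
                    * ls_noise[i, t, j]
                )
                ls_rows.append((d, cy, cat, head))
    livestock = pd.DataFrame(ls_rows, columns=list(core.LIVESTOCK_COLUMNS))

    # --- deposition grid: coarse, monthly, deterministic smooth field
    dep_lat = np.arange(_LAT_SPAN[0], _LAT_SPAN[1] + 1e-6, 1.9)
    dep_lon = np.arange(_LON_SPAN[0], _LON_SPAN[1] + 1e-6, 2.5)
    dep_years = list(range(config.dep_start_year, config.dep_end_year + 1))
    times = pd.to_datetime([f"{y}-{m:02d}-01" for y in dep_years for m in range(1, 13)])
    lat_norm = (dep_lat - dep_lat.mean()) / max(np.ptp(dep_lat), 1e-9)
    annual = np.maximum(
        config.dep_base
        + config.dep_gradient * lat_norm[:, None]
        + config.dep_trend * (np.array(dep_years)[:, None, None] - config.dep_start_year),
        0.05,
    ) * np.ones((len(dep_years), len(dep_lat), len(dep_lon)))
    monthly = np.repeat(annual, 12, axis=0) * np.tile(_MONTH_WEIGHTS, len(dep_years))[:, None, None]
    deposition = xr.DataArray(
        monthly,
        coords={"time": times, "lat": dep_lat, "lon": dep_lon},
        dims=("time", "lat", "lon"),
        name="n_deposition",
        attrs={"units": "kg N ha-1 month-1"},
    )

    # --- gridded manure product: finer grid, annual
    man_lat = np.arange(_LAT_SPAN[0], _LAT_SPAN[1] + 1e-6, 1.0)
    man_lon = np.arange(_LON_SPAN[0], _LON_SPAN[1] + 1e-6, 1.0)
    man_years = list(range(config.start_year, config.manure_grid_end_year + 1))
    lon_norm = (man_lon - man_lon.mean()) / max(np.ptp(man_lon), 1e-9)
    man_vals = np.maximum(
        config.manure_grid_base
        + config.manure_grid_gradient * lon_norm[None, None, :]
        + config.manure_grid_trend * (np.array(man_years)[:, None, None] - config.start_year),
        0.0,
    ) * np.ones((len(man_years), len(man_lat), len(man_lon)))
    manure_grid = xr.DataArray(
        man_vals,
        coords={"year": man_years, "lat": man_lat, "lon": man_lon},
        dims=("year", "lat", "lon"),
        name="manure_application",
        attrs={"units": "kg N ha-1 yr-1"},
    )

    coefficients = default_coefficients(crops_used["crop_id"], categories)
    meta = {
        "config": asdict(config),
        "truth": {
            "fert_factor": dict(zip(districts, fert_factor.tolist())),
            "fert_curve": dict(zip(years, curve.tolist())),
        },
    }
    return InputBundle(
        land_use=land_use,
        fertilizer=fertilizer,
        crops=crops,
        livestock=livestock,
        deposition=deposition,
        manure_grid=manure_grid,
        coefficients=coefficients,
        centroids=centroids,
        region_mapping=region_mapping,
        meta=meta,
    )


def collapsed_bundle(base: InputBundle) -> InputBundle:
    """A copy of ``base`` on which all 12 ensemble members coincide.

    The two N-content sources are made identical, every crop is rendered
    non-fixing, and all three manure pathways are zeroed (no livestock,
    zero gridded product), so the manure / BNF / uptake axes collapse.
    Useful as a degenerate-ensemble control: the surplus spread (IQR, sd)
    must vanish identically.
    """
    cf = base.coefficients
    bnf = cf.bnf.reset_index().assign(pct_ndfa=0.0, area_rate=0.0)
    nc = cf.n_content.reset_index()
    fao = nc[nc["source"] == "FAO"].set_index("crop_id")["n_content"]
    nc["n_content"] = nc["crop_id"].map(fao)
    coefficients = CoefficientSet(
        bnf=bnf, n_content=nc, manure=cf.manure.reset_index(),
        prosys_shares=dict(cf.prosys_shares), policy=cf.policy,
    )
    manure_grid = xr.zeros_like(base.manure_grid)
    manure_grid.attrs = dict(base.manure_grid.attrs)
    return InputBundle(
        land_use=base.land_use, fertilizer=base.fertilizer, crops=base.crops,
        livestock=base.livestock.assign(headcount=0.0),
        deposition=base.deposition, manure_grid=manure_grid,
        coefficients=coefficients, centroids=base.centroids,
        region_mapping=base.region_mapping, meta=dict(base.meta),
    )


# ---------------------------------------------------------------------------
# independent ground-truth oracle


def ground_truth_surplus(
    bundle: InputBundle,
    member: EnsembleMember | str,
    basis: str = "net",
    *,
    nhi_mode: str = "multiply",
    through_year: int | None = None,
) -> ComponentSeries:
    """Surplus for one member by direct straight-line arithmetic.

    Recomputes every component from the bundle tables with explicit loops
    and no pipeline helpers; serves as the oracle in end-to-end recovery
    tests.
    """
    if isinstance(member, str):
        member = core.member_by_id(member)
    if basis not in ("net", "gross"):
        raise ValueError(f"unknown basis {basis!r}")
    if nhi_mode not in ("multiply", "divide"):
        raise ValueError(f"unknown nhi_mode {nhi_mode!r}")

    lu = {(r.district_id, r.year): r for r in bundle.land_use.itertuples()}
    years = sorted({y for (_, y) in lu})
    through = int(through_year if through_year is not None else max(years))
    fert = {(r.district_id, r.year): r.total_n_applied for r in bundle.fertilizer.itertuples()}

    crop_rows: dict = {}
    for r in bundle.crops.itertuples():
        crop_rows.setdefault((r.district_id, r.year), []).append((r.crop_id, r.harvested_area, r.production))

    census: dict = {}
    for r in bundle.livestock.itertuples():
        census.setdefault((r.district_id, r.category_id), []).append((r.census_year, r.headcount))
    for k in census:
        census[k].sort()

    cf = bundle.coefficients
    bnf_c = {i: r for i, r in cf.bnf.iterrows()}
    ncont = {(i[0], i[1]): r["n_content"] for i, r in cf.n_content.iterrows()}
    man_c = {i: r for i, r in cf.manure.iterrows()}
    shares = dict(cf.prosys_shares)

    # nearest grid cell per district on both grids, explicit scan with
    # strict-< so ties keep the lowest (lat, lon) index
    def nearest(lat0, lon0, lats, lons):
        best, best_d = None, None
        for i, la in enumerate(lats):
            for j, lo in enumerate(lons):
                p1, l1, p2, l2 = map(math.radians, (lat0, lon0, la, lo))
                a = math.sin((p2 - p1) / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin((l2 - l1) / 2) ** 2
                d = 2 * 6371.0088 * math.asin(math.sqrt(a))
                if best_d is None or d < best_d:
                    best, best_d = (i, j), d
        return best

    dep_lats = [float(v) for v in bundle.deposition["lat"].values]
    dep_lons = [float(v) for v in bundle.deposition["lon"].values]
    dep_t = pd.DatetimeIndex(bundle.deposition["time"].values)
    dep_vals = bundle.deposition.values
    man_lats = [float(v) for v in bundle.manure_grid["lat"].values]
    man_lons = [float(v) for v in bundle.manure_grid["lon"].values]
    man_years = [int(v) for v in bundle.manure_grid["year"].values]
    man_vals = bundle.manure_grid.values

    dep_annual: dict = {}
    man_rate: dict = {}
    for r in bundle.centroids.itertuples():
        i, j = nearest(r.latitude, r.longitude, dep_lats, dep_lons)
        per_year: dict = {}
        for t in range(len(dep_t)):
            per_year[dep_t[t].year] = per_year.get(dep_t[t].year, 0.0) + float(dep_vals[t, i, j])
        dep_annual[r.district_id] = per_year
        i, j = nearest(r.latitude, r.longitude, man_lats, man_lons)
        man_rate[r.district_id] = {y: float(man_vals[t, i, j]) for t, y in enumerate(man_years)}

    def carry(table: dict, year: int) -> float:
        if year in table:
            return table[year]
        last = max(table)
        if year > last:
            return table[last]
        raise KeyError(f"year {year} before gridded coverage")

    def interp_census(pairs, year):
        if year <= pairs[0][0]:
            return pairs[0][1]
        if year >= pairs[-1][0]:
            return pairs[-1][1]
        for (y0, v0), (y1, v1) in zip(pairs, pairs[1:]):
            if y0 <= year <= y1:
                return v0 + (v1 - v0) * (year - y0) / (y1 - y0)
        raise AssertionError

    source = member.uptake_source
    out = {}
    for (d, y), r in lu.items():
        area = r.net_cropped_area if basis == "net" else r.gross_cropped_area

        dep_load = carry(dep_annual[d], y) * r.district_area * r.cropland_fraction
        n_dep = dep_load / area if area > 0 else 0.0
        n_fert = fert[(d, y)] / area if area > 0 else 0.0

        n_crop = 0.0
        n_bnf = 0.0
        for crop_id, ca, prod in crop_rows.get((d, y), []):
            nc = ncont.get((crop_id, source))
            if nc is not None:
                n_crop += prod * nc
            b = bnf_c.get(crop_id)
            if b is None:
                continue
            if member.bnf_method == "AREA":
                n_bnf += ca * b["area_rate"]
            elif nc is not None and ca > 0:
                y_n = prod * nc / ca  # crop N yield, kg N / ha
                term = b["pct_ndfa"] * y_n
                term = term * b["nhi"] if nhi_mode == "multiply" else term / b["nhi"]
                n_bnf += term * b["bgn"] * ca
        n_crop = n_crop / area if area > 0 else 0.0
        n_bnf = n_bnf / area if area > 0 else 0.0

        if member.manure_method == "GRIDDED":
            n_man = carry(man_rate[d], y) * r.net_cropped_area / area if area > 0 else 0.0
        else:
            n_man = 0.0
            for cat in sorted({c for (dd, c) in census if dd == d}):
                mc = man_c.get(cat)
                if mc is None:
                    continue
                head = interp_census(census[(d, cat)], y)
                n_ex = mc["n_rate"] * mc["tam"] / 1000.0 * 365.0
                per_ha = n_ex * head / area if area > 0 else 0.0
                if member.manure_method == "CENSUS_GLOBAL":
                    f_m = 0.0
                    for prosys, share in shares.items():
                        f_m += share * mc[f"f_mt_{prosys}"] * (1 - mc[f"f_mo_{prosys}"]) * (1 - mc[f"f_loss_{prosys}"])
                    n_man += per_ha * f_m
                elif cat in core.RUMINANT_CATEGORIES:
                    n_man += per_ha * (1.0 - (mc["am_cn"] + mc["am_cl"] + mc["am_fl"]))

        out[(d, y)] = n_dep + n_fert + n_bnf + n_man - n_crop

    values = pd.Series(out)
    values.index.set_names(["district_id", "year"], inplace=True)
    return ComponentSeries("NS", f"truth-{member.member_id}_{basis}", basis, values)
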