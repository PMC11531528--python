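"""Spatial aggregation of district series to state / basin / sub-basin /
national scales.

Regions are abstract district -> region assignments (no geometry).  Rates
aggregate as cropped-area-weighted means: the region total load is
sum over districts of rate x weight area, and the region rate is that total
divided by the summed weight area, so loads are conserved exactly.  Weights
default to the year-specific cropped area of the series' basis; an
equal-weight mode is available for sensitivity.

For ensembles, aggregation is applied member-wise *before* summarizing, so
a region's IQR reflects methodological spread, not inter-district spread.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import core, ensemble as ens_mod
from .core import ComponentSeries, NET

SCHEMES = ("state", "basin", "subbasin", "national")


def national_mapping(districts) -> pd.DataFrame:
    """The trivial single-region scheme covering all districts."""
    return pd.DataFrame({"district_id": list(districts), "scheme": "national", "region_id": "ALL"})


def _scheme_mapping(mapping: pd.DataFrame, scheme: str, districts) -> pd.Series:
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    sub = mapping[mapping["scheme"] == scheme]
    if sub.empty and scheme == "national":
        sub = national_mapping(districts)
    if sub["district_id"].duplicated().any():
        dups = sub.loc[sub["district_id"].duplicated(), "district_id"].tolist()
        raise ValueError(f"districts mapped to multiple {scheme} regions: {dups[:5]}")
    lookup = sub.set_index("district_id")["region_id"]
    missing = sorted(set(districts) - set(lookup.index))
    if missing:
        warnings.warn(f"{len(missing)} districts lack a {scheme} mapping and are excluded: {missing[:5]}", stacklevel=3)
    return lookup


def aggregate(
    series: ComponentSeries | pd.Series,
    mapping: pd.DataFrame,
    land_use: pd.DataFrame,
    scheme: str,
    *,
    basis: str = NET,
    weights: str = "area",
) -> pd.DataFrame:
    """Aggregate a (district, year) rate series to regions.

    Returns a frame indexed by (region_id, year) with columns
    ``total_load`` (kg N yr-1), ``weight_area`` (ha) and ``rate``
    (kg N ha-1 yr-1 = total_load / weight_area).
    """
    if isinstance(series, ComponentSeries):
        basis = series.basis
        series = series.values
    if weights not in ("area", "equal"):
        raise ValueError(f"unknown weight mode {weights!r}")
    area = core.basis_area(land_use, basis)
    if weights == "equal":
        area = pd.Series(1.0, index=area.index, name="area")
    df = series.rename("rate").to_frame()
    df["weight"] = area.reindex(df.index)
    districts = df.index.get_level_values("district_id").unique()
    lookup = _scheme_mapping(mapping, scheme, districts)
    df["region_id"] = df.index.get_level_values("district_id").map(lookup)
    df = df.dropna(subset=["region_id"])
    df["load"] = df["rate"] * df["weight"]
    years = df.index.get_level_values("year")
    out = df.groupby(["region_id", years])[["load", "weight"]].sum()
    out.index.set_names(["region_id", "year"], inplace=True)
    zero = (out["weight"] == 0) & (out["load"] != 0)
    if zero.any():
        warnings.warn(f"{int(zero.sum())} region-years with zero total weight; rate flagged missing", stacklevel=2)
    out["rate"] = np.where(out["weight"] > 0, out["load"] / out["weight"].replace(0, np.nan), np.nan)
    out.loc[(out["weight"] == 0) & (out["load"] == 0), "rate"] = 0.0
    return out.rename(columns={"load": "total_load", "weight": "weight_area"}).sort_index()


def aggregate_ensemble(
    ensemble: "ens_mod.SurplusEnsemble",
    mapping: pd.DataFrame,
    land_use: pd.DataFrame,
    scheme: str,
    *,
    weights: str = "area",
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Member-wise aggregation plus regional uncertainty summaries.

    Returns ``(per_member, summary)``: the per-member region frames from
    :func:`aggregate`, and the mean / Q1 / Q3 / IQR / sd of the 12 regional
    rate series (aggregate-then-summarize).
    """
    per_member = {
        member_id: aggregate(values, mapping, land_use, scheme, basis=ensemble.basis, weights=weights)
        for member_id, values in ensemble.members.items()
    }
    rates = pd.DataFrame({mid: frame["rate"] for mid, frame in per_member.items()}).sort_index(axis=1)
    return per_member, ens_mod.summarize(rates)
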