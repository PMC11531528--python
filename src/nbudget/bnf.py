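"""Biological N fixation (BNF) by yield-based and area-based methods.

Yield-based: per fixing crop, the fixed N is %Ndfa x Y x NHI x BGN, with Y
the crop's N yield (kg N ha-1 yr-1, from production x N content / harvested
area), NHI the nitrogen harvest index and BGN the below-ground multiplier
for roots, nodules and rhizodeposition.  Crop contributions are
area-weighted (harvested area / basis area) into a district rate, which
makes the method dimensionally parallel to the area-based one.

Area-based: per fixing crop, harvested area x a literature fixation rate
(kg N ha-1 yr-1), summed and divided by the basis area.

``nhi_mode`` controls whether NHI multiplies the N yield (the printed form,
default) or divides it (the form that recovers total plant N from harvested
N in the source literature); the choice is recorded in the method tag.
"""

from __future__ import annotations

import warnings

import pandas as pd

from . import core
from .core import ComponentSeries, NET

NHI_MODES = ("multiply", "divide")


def _to_rate(load: pd.Series, land_use: pd.DataFrame, basis: str) -> pd.Series:
    """Spread a district-year load over the basis area; empty cells are 0."""
    area = core.basis_area(land_use, basis)
    load = load.reindex(area.index, fill_value=0.0)
    rate = load / area.where(area > 0, other=pd.NA)
    return rate.fillna(0.0).astype(float)


def bnf_yield(
    crops: pd.DataFrame,
    coefficients: core.CoefficientSet,
    n_content_source: str,
    land_use: pd.DataFrame,
    basis: str = NET,
    *,
    nhi_mode: str = "multiply",
) -> ComponentSeries:
    """Yield-based BNF, kg N ha-1 yr-1 of the basis area.

    The crop N yield uses the same N-content source as the paired uptake
    estimate, so the two yield-based members differ wherever the two
    content tables differ.  Since Y x harvested area = production x
    N content, the crop load is computed directly from production, which
    sidesteps 0/0 for unharvested crops.
    """
    core.check_basis(basis)
    if nhi_mode not in NHI_MODES:
        raise ValueError(f"unknown nhi_mode {nhi_mode!r}; expected one of {NHI_MODES}")
    breg = coefficients.bnf_registry()
    creg = coefficients.n_content_registry(n_content_source)
    keep = set(breg.resolve(crops["crop_id"].unique())) & set(creg.resolve(crops["crop_id"].unique()))
    sub = crops[crops["crop_id"].isin(keep) & (crops["harvested_area"] > 0)].copy()

    coefs = breg.frame
    harvested_n = sub["production"] * sub["crop_id"].map(creg.frame["n_content"])
    fixed = sub["crop_id"].map(coefs["pct_ndfa"]) * harvested_n
    nhi = sub["crop_id"].map(coefs["nhi"])
    fixed = fixed * nhi if nhi_mode == "multiply" else fixed / nhi
    sub["fixed_n"] = fixed * sub["crop_id"].map(coefs["bgn"])
    load = sub.groupby(["district_id", "year"])["fixed_n"].sum()
    rate = _to_rate(load, land_use, basis)
    return ComponentSeries("BNF", f"bnf-yield-{n_content_source.lower()}-{nhi_mode}_{basis}", basis, rate)


def bnf_area(
    crops: pd.DataFrame,
    coefficients: core.CoefficientSet,
    land_use: pd.DataFrame,
    basis: str = NET,
) -> ComponentSeries:
    """Area-based BNF: sum_c harvested_area_c x rate_c / basis area."""
    core.check_basis(basis)
    breg = coefficients.bnf_registry()
    keep = breg.resolve(crops["crop_id"].unique())
    sub = crops[crops["crop_id"].isin(keep)].copy()

    gca = land_use.set_index(["district_id", "year"])["gross_cropped_area"]
    by_dy = sub.groupby(["district_id", "year"])["harvested_area"].sum()
    # relative slack: tabulated areas round-trip at ~6 significant digits
    over = by_dy[by_dy > gca.reindex(by_dy.index) * (1 + 1e-5)]
    if len(over):
        warnings.warn(
            f"{len(over)} district-years with summed crop area exceeding gross cropped area",
            stacklevel=2,
        )

    sub["fixed_n"] = sub["harvested_area"] * sub["crop_id"].map(breg.frame["area_rate"])
    load = sub.groupby(["district_id", "year"])["fixed_n"].sum()
    rate = _to_rate(load, land_use, basis)
    return ComponentSeries("BNF", f"bnf-area_{basis}", basis, rate)
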