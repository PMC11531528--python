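"""Fertilizer input (FERT) and crop N removal (CROP) components.

FERT divides the district's total synthetic-N application by the chosen
cropped-area basis; no crop-specific allocation is attempted, matching the
single district-total fertilizer figure available in district panels.

CROP multiplies crop-wise production by a per-crop N content from one of two
coefficient sources (FAO or BOUWMAN) and divides the summed harvested-N load
by the same area basis.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import core
from .core import ComponentSeries, NET


def _rate_from_load(load: pd.Series, area: pd.Series, *, what: str, policy: str) -> pd.Series:
    """load / area with zero-area handling per the missing-value policy."""
    load, area = load.align(area, join="inner")
    bad = (area == 0) & (load > 0)
    if bad.any():
        msg = f"{int(bad.sum())} district-years with zero area but nonzero {what}"
        if policy == "error":
            raise ValueError(msg)
        warnings.warn(msg + "; flagged missing (dropped)", stacklevel=3)
    rate = np.where(load > 0, load / area.replace(0, np.nan), 0.0)
    return pd.Series(rate, index=load.index)[~bad]


def fertilizer_rate(
    fertilizer: pd.DataFrame,
    land_use: pd.DataFrame,
    basis: str = NET,
    *,
    policy: str = "skip",
) -> ComponentSeries:
    """Total N fertilizer application rate, kg N ha-1 yr-1 of the basis area.

    The net-basis rate is the headline application rate; the gross-basis
    ("gross fertilizer application rate") divides by the total cropped area
    and is therefore never larger.
    """
    core.check_basis(basis)
    load = fertilizer.set_index(["district_id", "year"])["total_n_applied"].sort_index()
    if (load < 0).any():
        raise ValueError("negative total_n_applied; run validate_panel first")
    area = core.basis_area(land_use, basis)
    rate = _rate_from_load(load, area, what="fertilizer", policy=policy)
    return ComponentSeries("FERT", f"fert_{basis}", basis, rate)


def crop_n_uptake(
    crops: pd.DataFrame,
    coefficients: core.CoefficientSet,
    source: str,
    land_use: pd.DataFrame,
    basis: str = NET,
) -> ComponentSeries:
    """Harvested-N removal: sum_c production_c x n_content(c, source) / area.

    Crops absent from the N-content registry for ``source`` are handled per
    the coefficient set's missing-coefficient policy (skip => contribute 0).
    """
    core.check_basis(basis)
    reg = coefficients.n_content_registry(source)
    keep = reg.resolve(crops["crop_id"].unique())
    sub = crops[crops["crop_id"].isin(keep)].copy()
    sub["harvested_n"] = sub["production"] * sub["crop_id"].map(reg.frame["n_content"])
    load = sub.groupby(["district_id", "year"])["harvested_n"].sum()
    # district-years with no listed crop at all still belong to the panel
    full = core.basis_area(land_use, basis)
    load = load.reindex(full.index, fill_value=0.0).sort_index()
    rate = _rate_from_load(load, full, what="crop uptake", policy=coefficients.policy)
    return ComponentSeries("CROP", f"crop-{source.lower()}_{basis}", basis, rate)
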