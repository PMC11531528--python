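"""Consistency checks against reference country-level N budgets.

District ensembles are collapsed to national annual series (area-weighted
per-ha rates, or total loads convertible to Tg N), then compared with
published country-level series by the coefficient of determination of an
ordinary-least-squares linear fit, reported as the mean and standard
deviation of the 12 per-member R2 values.  A coverage check flags, per
year, whether the reference value falls inside the ensemble mean +/- one
standard deviation band.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from . import aggregate as agg_mod
from . import core
from .ensemble import SurplusEnsemble

KG_PER_TG = 1.0e9


def national_series(
    ensemble: SurplusEnsemble,
    land_use: pd.DataFrame,
    *,
    mode: str = "per_ha",
    weights: str = "area",
) -> pd.DataFrame:
    """Annual national series per member (year x member_id).

    ``mode='per_ha'`` gives the area-weighted national mean rate
    (kg N ha-1 yr-1); ``mode='total'`` gives the summed national load
    (kg N yr-1; divide by 1e9 for Tg N yr-1).
    """
    if mode not in ("per_ha", "total"):
        raise ValueError(f"unknown mode {mode!r}")
    if not ensemble.members:
        raise ValueError("empty ensemble")
    districts = next(iter(ensemble.members.values())).index.get_level_values("district_id").unique()
    mapping = agg_mod.national_mapping(districts)
    per_member, _ = agg_mod.aggregate_ensemble(ensemble, mapping, land_use, "national", weights=weights)
    col = "rate" if mode == "per_ha" else "total_load"
    out = pd.DataFrame({mid: frame.xs("ALL", level="region_id")[col] for mid, frame in per_member.items()})
    out.index.name = "year"
    return out.sort_index(axis=1)


def to_tg(total_kg: pd.Series | pd.DataFrame):
    """kg N -> Tg N (x 1e-9), exact."""
    return total_kg * 1.0e-9


def r_squared(series_a: pd.Series, series_b: pd.Series) -> float:
    """R2 of the OLS linear fit of ``series_b`` on ``series_a``.

    Aligned on common years (>= 3 required).  With an intercept this
    equals the squared Pearson correlation, so it is invariant to affine
    rescaling of either series.  Zero variance in either series leaves R2
    undefined: flagged with a warning, returned as NaN.
    """
    a, b = series_a.align(series_b, join="inner")
    mask = a.notna() & b.notna()
    a, b = a[mask].astype(float), b[mask].astype(float)
    if len(a) < 3:
        raise ValueError(f"need >= 3 overlapping years, got {len(a)}")
    if np.ptp(a.to_numpy()) == 0 or np.ptp(b.to_numpy()) == 0:
        warnings.warn("zero variance in one series; R2 undefined", stacklevel=2)
        return float("nan")
    fit = stats.linregress(a.to_numpy(), b.to_numpy())
    return float(fit.rvalue**2)


def r_squared_ensemble(national: pd.DataFrame, reference: pd.Series) -> dict:
    """Per-member R2 against a reference series, with mean and sd.

    ``national`` is a year x member frame (from :func:`national_series`);
    the reference must share its units and scale.
    """
    per_member = {mid: r_squared(national[mid], reference) for mid in national.columns}
    vals = np.array([v for v in per_member.values() if not np.isnan(v)])
    return {
        "per_member": per_member,
        "mean": float(vals.mean()) if len(vals) else float("nan"),
        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
        "n_members": int(len(vals)),
    }


def coverage_check(national: pd.DataFrame, reference: pd.Series) -> pd.DataFrame:
    """Whether the reference lies within mean +/- 1 sd of the 12 members.

    Returns per overlapping year the ensemble mean, sd, reference value and
    a containment flag; the containment fraction is stored in
    ``frame.attrs['containment_fraction']``.
    """
    mean = national.mean(axis=1)
    sd = national.std(axis=1, ddof=1)
    ref = reference.reindex(mean.index).dropna()
    mean, sd = mean.reindex(ref.index), sd.reindex(ref.index)
    contained = (ref >= mean - sd) & (ref <= mean + sd)
    out = pd.DataFrame({"mean": mean, "sd": sd, "reference": ref, "contained": contained})
    out.attrs["containment_fraction"] = float(contained.mean()) if len(out) else float("nan")
    return out
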