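"""The 12-member N-surplus ensemble and its uncertainty summaries.

Per district and year the surplus is

    NS = N_DEP + N_FERT + N_BNF + N_MAN - N_CROP   (kg N ha-1 yr-1)

and may be negative.  Methodological uncertainty is represented by the
Cartesian product of one fertilizer estimate, one deposition estimate,
three manure estimates (census x global fractions, census x India
fractions, gridded product), two BNF methods (yield- and area-based) and
two N-removal coefficient sources (FAO, BOUWMAN): 3 x 2 x 2 = 12 members,
equal-weight by construction.

Summaries per (district, year): mean, Q1, Q3, IQR = Q3 - Q1, and the
sample standard deviation (n - 1 denominator); quartiles use linear
interpolation of order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bnf as bnf_mod
from . import core, crops, deposition, manure
from .core import BasisMismatchError, ComponentSeries, EnsembleMember, InputBundle, NET


def member_surplus(
    dep: ComponentSeries,
    fert: ComponentSeries,
    bnf: ComponentSeries,
    man: ComponentSeries,
    crop: ComponentSeries,
) -> ComponentSeries:
    """One member's surplus from its five components.

    All components must share the area basis; mixing NCA- and
    GCA-denominated series raises :class:`BasisMismatchError`.
    """
    parts = {"DEP": dep, "FERT": fert, "BNF": bnf, "MAN": man, "CROP": crop}
    for name, cs in parts.items():
        if cs.component != name:
            raise ValueError(f"expected component {name}, got {cs.component}")
    bases = {cs.basis for cs in parts.values()}
    if len(bases) > 1:
        raise BasisMismatchError(f"components on mixed area bases {sorted(bases)}")
    idx = dep.values.index
    for name, cs in parts.items():
        if not cs.values.index.equals(idx):
            raise ValueError(f"{name} coverage differs from DEP; align components first")
    ns = dep.values + fert.values + bnf.values + man.values - crop.values
    tag = "+".join(cs.method_tag for cs in parts.values())
    return ComponentSeries("NS", tag, dep.basis, ns)


@dataclass
class SurplusEnsemble:
    """Twelve member surplus series plus the components they combine."""

    basis: str
    members: dict[str, pd.Series]
    components: dict[str, ComponentSeries] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = {m.member_id for m in core.enumerate_members()}
        if set(self.members) != expected:
            raise ValueError(f"ensemble must hold exactly the 12 members; got {sorted(self.members)}")

    def frame(self) -> pd.DataFrame:
        """Members as columns, (district_id, year) as rows."""
        return pd.DataFrame(self.members).sort_index(axis=1)

    def member(self, member: EnsembleMember | str) -> pd.Series:
        member_id = member if isinstance(member, str) else member.member_id
        return self.members[member_id]


def summarize(ensemble: SurplusEnsemble | pd.DataFrame) -> pd.DataFrame:
    """Per-(district, year) mean, Q1, Q3, IQR and sd across the 12 members.

    Cells where any member is missing are flagged (``complete`` False) and
    summarized over the members present.
    """
    wide = ensemble.frame() if isinstance(ensemble, SurplusEnsemble) else ensemble
    arr = wide.to_numpy(dtype=float)
    complete = ~np.isnan(arr).any(axis=1)
    q1 = np.nanpercentile(arr, 25, axis=1)
    q3 = np.nanpercentile(arr, 75, axis=1)
    out = pd.DataFrame(
        {
            "mean": np.nanmean(arr, axis=1),
            "q1": q1,
            "q3": q3,
            "iqr": q3 - q1,
            "sd": np.nanstd(arr, axis=1, ddof=1),
            "complete": complete,
        },
        index=wide.index,
    )
    return out


def build_ensemble(
    bundle: InputBundle,
    basis: str = NET,
    *,
    nhi_mode: str = "multiply",
    through_year: int | None = None,
    cutoff_km: float | None = None,
) -> SurplusEnsemble:
    """Run every stage and assemble the 12-member surplus ensemble.

    Deposition and fertilizer are computed once and shared across members;
    the deposition series (and the gridded manure product) are carried
    forward at a constant rate from their final covered year through the
    panel's last year.
    """
    core.check_basis(basis)
    lu = bundle.land_use
    through = int(through_year if through_year is not None else lu["year"].max())
    coeffs = bundle.coefficients

    annual_dep = deposition.annualize(bundle.deposition)
    flux = deposition.to_districts(annual_dep, bundle.centroids, cutoff_km=cutoff_km)
    if through > int(flux.index.get_level_values("year").max()):
        flux = deposition.extend_constant(flux, through)
    panel_idx = core.basis_area(lu, basis).index
    flux = flux.reindex(panel_idx).dropna()
    dep = deposition.cropland_deposition(flux, lu, basis=basis)

    fert = crops.fertilizer_rate(bundle.fertilizer, lu, basis)

    crop_by_source = {s: crops.crop_n_uptake(bundle.crops, coeffs, s, lu, basis) for s in core.UPTAKE_SOURCES}
    bnf_by_method = {
        ("YIELD", s): bnf_mod.bnf_yield(bundle.crops, coeffs, s, lu, basis, nhi_mode=nhi_mode)
        for s in core.UPTAKE_SOURCES
    }
    area_series = bnf_mod.bnf_area(bundle.crops, coeffs, lu, basis)
    for s in core.UPTAKE_SOURCES:
        bnf_by_method[("AREA", s)] = area_series

    man_by_method = {
        "CENSUS_GLOBAL": manure.manure_census(bundle.livestock, coeffs, lu, "CENSUS_GLOBAL", basis),
        "CENSUS_INDIA": manure.manure_census(bundle.livestock, coeffs, lu, "CENSUS_INDIA", basis),
        "GRIDDED": manure.manure_from_grid(
            bundle.manure_grid, bundle.centroids, lu, basis, through_year=through, cutoff_km=cutoff_km
        ),
    }

    members: dict[str, pd.Series] = {}
    components: dict[str, ComponentSeries] = {"DEP": dep, "FERT": fert}
    for s, cs in crop_by_source.items():
        components[f"CROP:{s}"] = cs
    for (method, s), cs in bnf_by_method.items():
        components[f"BNF:{method}:{s}"] = cs
    for method, cs in man_by_method.items():
        components[f"MAN:{method}"] = cs

    for m in core.enumerate_members():
        try:
            ns = member_surplus(
                dep,
                fert,
                bnf_by_method[(m.bnf_method, m.uptake_source)],
                man_by_method[m.manure_method],
                crop_by_source[m.uptake_source],
            )
        except Exception as exc:
            raise RuntimeError(f"ensemble member {m.member_id} failed: {exc}") from exc
        members[m.member_id] = ns.values

    meta = {
        "basis": basis,
        "nhi_mode": nhi_mode,
        "through_year": through,
        "extension_rule": "constant carry-forward of last covered year (deposition and gridded manure)",
        "census_annualization": "linear interpolation, flat extrapolation",
        "prosys_shares": dict(coeffs.prosys_shares),
        "missing_coefficient_policy": coeffs.policy,
        "members": {
            m.member_id: {
                "manure_method": m.manure_method,
                "bnf_method": m.bnf_method,
                "uptake_source": m.uptake_source,
            }
            for m in core.enumerate_members()
        },
    }
    return SurplusEnsemble(basis, members, components, meta)
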