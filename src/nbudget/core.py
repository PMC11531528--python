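"""Shared domain types, unit conventions, coefficient registries and panel
validation for the nitrogen-budget pipeline.

Unit conventions are fixed internally and every reader converts at the
boundary:

* masses: kg N
* areas: ha
* rates: kg N ha-1 yr-1 (of the chosen area basis)

The two area bases are the net cropped area (NCA, land sown at least once in
a year) and the gross cropped area (GCA, summed over multiple croppings;
GCA >= NCA).  Every computed component records its basis so that series on
different denominators can never be mixed silently.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# constants

NET = "net"
GROSS = "gross"
BASES = (NET, GROSS)

#: budget components; all are gross fluxes >= 0, only the surplus ("NS")
#: may be negative.
COMPONENTS = ("DEP", "FERT", "BNF", "MAN", "CROP", "NS")
NONNEGATIVE_COMPONENTS = ("DEP", "FERT", "BNF", "MAN", "CROP")

LIVESTOCK_CATEGORIES = ("cattle", "buffalo", "poultry", "chickens", "pigs", "goats", "sheep")
#: categories entering the India-specific manure-application pathway
RUMINANT_CATEGORIES = ("sheep", "goats", "buffalo", "cattle")

CENSUS_INTERVAL = 5

MANURE_METHODS = ("CENSUS_GLOBAL", "CENSUS_INDIA", "GRIDDED")
BNF_METHODS = ("YIELD", "AREA")
UPTAKE_SOURCES = ("FAO", "BOUWMAN")
PRODUCTION_SYSTEMS = ("irrigated", "rainfed")

_MANURE_CODE = {"CENSUS_GLOBAL": "g", "CENSUS_INDIA": "i", "GRIDDED": "z"}
_BNF_CODE = {"YIELD": "y", "AREA": "a"}
_UPTAKE_CODE = {"FAO": "f", "BOUWMAN": "b"}

# column schemas for the delimited-text interfaces (documented in
# docs/schemas.md)
LAND_USE_COLUMNS = (
    "district_id", "year", "net_cropped_area", "gross_cropped_area",
    "district_area", "cropland_fraction",
)
FERTILIZER_COLUMNS = ("district_id", "year", "total_n_applied")
CROP_COLUMNS = ("district_id", "year", "crop_id", "harvested_area", "production")
LIVESTOCK_COLUMNS = ("district_id", "census_year", "category_id", "headcount")
BNF_COEF_COLUMNS = ("crop_id", "pct_ndfa", "nhi", "bgn", "area_rate")
N_CONTENT_COLUMNS = ("crop_id", "source", "n_content")
MANURE_COEF_COLUMNS = (
    "category_id", "n_rate", "tam",
    "f_mt_irrigated", "f_mo_irrigated", "f_loss_irrigated",
    "f_mt_rainfed", "f_mo_rainfed", "f_loss_rainfed",
    "am_cn", "am_cl", "am_fl",
)
CENTROID_COLUMNS = ("district_id", "latitude", "longitude")
MAPPING_COLUMNS = ("district_id", "scheme", "region_id")


class MissingCoefficientError(KeyError):
    """A crop or livestock category has no coefficient under policy='error'."""


class BasisMismatchError(ValueError):
    """Component series on different area bases were combined."""


# ---------------------------------------------------------------------------
# component series


def check_basis(basis: str) -> str:
    if basis not in BASES:
        raise ValueError(f"unknown area basis {basis!r}; expected one of {BASES}")
    return basis


def basis_area(land_use: pd.DataFrame, basis: str) -> pd.Series:
    """Area denominator (ha) per (district_id, year) for the chosen basis."""
    check_basis(basis)
    col = "net_cropped_area" if basis == NET else "gross_cropped_area"
    out = land_use.set_index(["district_id", "year"])[col].sort_index()
    out.name = "area"
    return out


@dataclass(frozen=True)
class ComponentSeries:
    """One budget component on a (district_id, year) panel.

    ``values`` holds kg N ha-1 yr-1 of the declared area basis.  Components
    other than the surplus ("NS") are gross fluxes and must be nonnegative.
    """

    component: str
    method_tag: str
    basis: str
    values: pd.Series

    def __post_init__(self) -> None:
        if self.component not in COMPONENTS:
            raise ValueError(f"unknown component {self.component!r}")
        check_basis(self.basis)
        v = self.values
        if not isinstance(v, pd.Series) or v.index.nlevels != 2:
            raise TypeError("values must be a Series indexed by (district_id, year)")
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            raise ValueError(f"{self.component}: non-finite values")
        if self.component in NONNEGATIVE_COMPONENTS and (v < 0).any():
            raise ValueError(f"{self.component}: negative flux values")
        object.__setattr__(self, "values", v.sort_index())
        self.values.index.set_names(["district_id", "year"], inplace=True)

    def to_frame(self) -> pd.DataFrame:
        out = self.values.rename("value_kgN_ha").reset_index()
        out["component"] = self.component
        out["method_tag"] = self.method_tag
        out["basis"] = self.basis
        return out


# ---------------------------------------------------------------------------
# ensemble members


@dataclass(frozen=True, order=True)
class EnsembleMember:
    """One combination of the three methodological axes."""

    manure_method: str
    bnf_method: str
    uptake_source: str

    def __post_init__(self) -> None:
        if self.manure_method not in MANURE_METHODS:
            raise ValueError(f"unknown manure method {self.manure_method!r}")
        if self.bnf_method not in BNF_METHODS:
            raise ValueError(f"unknown BNF method {self.bnf_method!r}")
        if self.uptake_source not in UPTAKE_SOURCES:
            raise ValueError(f"unknown uptake source {self.uptake_source!r}")

    @property
    def member_id(self) -> str:
        return (
            f"man-{_MANURE_CODE[self.manure_method]}"
            f"_bnf-{_BNF_CODE[self.bnf_method]}"
            f"_upt-{_UPTAKE_CODE[self.uptake_source]}"
        )


def enumerate_members() -> list[EnsembleMember]:
    """All 12 members: 3 manure x 2 BNF x 2 uptake, in canonical order."""
    return [
        EnsembleMember(m, b, u)
        for m, b, u in itertools.product(MANURE_METHODS, BNF_METHODS, UPTAKE_SOURCES)
    ]


def member_by_id(member_id: str) -> EnsembleMember:
    for m in enumerate_members():
        if m.member_id == member_id:
            return m
    raise KeyError(f"unknown ensemble member {member_id!r}")


# ---------------------------------------------------------------------------
# coefficient registry


class Registry:
    """Keyed coefficient table with a configurable missing-key policy.

    policy='skip' (default) excludes a missing crop/category from the budget
    with a warning, mirroring a budget restricted to the listed crops;
    policy='error' raises :class:`MissingCoefficientError`.
    """

    def __init__(self, frame: pd.DataFrame, key: str | Sequence[str], *, policy: str = "skip", name: str = "coefficients"):
        if policy not in ("skip", "error"):
            raise ValueError(f"unknown missing-coefficient policy {policy!r}")
        key = [key] if isinstance(key, str) else list(key)
        frame = frame.set_index(key) if not frame.index.names == key else frame
        if frame.index.has_duplicates:
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValueError(f"{name}: duplicate keys {dups[:5]}")
        self.frame = frame.sort_index()
        self.policy = policy
        self.name = name

    def lookup(self, key):
        """The unique record for ``key``; None (with a warning) under skip."""
        try:
            return self.frame.loc[key]
        except KeyError:
            if self.policy == "error":
                raise MissingCoefficientError(f"{self.name}: no entry for {key!r}") from None
            warnings.warn(f"{self.name}: no entry for {key!r}; excluded", stacklevel=2)
            return None

    def resolve(self, keys: Iterable) -> list:
        """Subset of ``keys`` present in the registry, applying the policy."""
        keys = list(dict.fromkeys(keys))
        present = [k for k in keys if k in self.frame.index]
        missing = [k for k in keys if k not in self.frame.index]
        if missing:
            if self.policy == "error":
                raise MissingCoefficientError(f"{self.name}: no entry for {missing}")
            warnings.warn(f"{self.name}: excluded {len(missing)} keys without coefficients: {missing[:5]}", stacklevel=2)
        return present


@dataclass
class CoefficientSet:
    """All per-crop and per-livestock parameters of the budget equations.

    * ``bnf`` — per crop: pct_ndfa (fraction of crop N from fixation), nhi
      (N harvest index), bgn (below-ground N multiplier), area_rate
      (kg N ha-1 yr-1 for the area-based method).
    * ``n_content`` — per (crop, source in {FAO, BOUWMAN}): kg N per kg
      harvested product.
    * ``manure`` — per livestock category: excretion rate n_rate
      (kg N (1000 kg animal mass)-1 day-1), typical animal mass tam (kg),
      manure fate fractions per production system (f_mt managed, f_mo other
      uses, f_loss volatilized) and India-specific fractions (am_cn lost in
      collection, am_cl construction, am_fl burnt as fuel).
    """

    bnf: pd.DataFrame
    n_content: pd.DataFrame
    manure: pd.DataFrame
    prosys_shares: Mapping[str, float] = field(default_factory=lambda: {"irrigated": 0.4, "rainfed": 0.6})
    policy: str = "skip"

    def __post_init__(self) -> None:
        self.bnf = _as_indexed(self.bnf, ["crop_id"])
        self.n_content = _as_indexed(self.n_content, ["crop_id", "source"])
        self.manure = _as_indexed(self.manure, ["category_id"])
        self.validate()

    def validate(self) -> None:
        b = self.bnf
        if (b[["pct_ndfa", "nhi", "bgn", "area_rate"]] < 0).any().any() or not np.isfinite(b.to_numpy(dtype=float)).all():
            raise ValueError("BNF coefficients must be finite and nonnegative")
        if (b["pct_ndfa"] > 1).any():
            raise ValueError("pct_ndfa must lie in [0, 1]")
        nc = self.n_content["n_content"]
        if ((nc < 0) | (nc >= 0.2)).any():
            raise ValueError("n_content must lie in [0, 0.2)")
        bad = set(self.n_content.index.get_level_values("source")) - set(UPTAKE_SOURCES)
        if bad:
            raise ValueError(f"unknown N-content sources {sorted(bad)}")
        m = self.manure
        frac_cols = [c for c in m.columns if c.startswith(("f_", "am_"))]
        if ((m[frac_cols] < 0) | (m[frac_cols] > 1)).any().any():
            raise ValueError("manure fate fractions must lie in [0, 1]")
        am_sum = m[["am_cn", "am_cl", "am_fl"]].sum(axis=1)
        if (am_sum > 1 + 1e-9).any():
            raise ValueError("am_cn + am_cl + am_fl must not exceed 1")
        total = sum(self.prosys_shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"production-system shares sum to {total}, not 1")

    def bnf_registry(self) -> Registry:
        return Registry(self.bnf, "crop_id", policy=self.policy, name="BNF coefficients")

    def n_content_registry(self, source: str) -> Registry:
        if source not in UPTAKE_SOURCES:
            raise ValueError(f"unknown N-content source {source!r}; expected one of {UPTAKE_SOURCES}")
        sub = self.n_content.xs(source, level="source")
        return Registry(sub, "crop_id", policy=self.policy, name=f"N content ({source})")

    def manure_registry(self) -> Registry:
        return Registry(self.manure, "category_id", policy=self.policy, name="manure coefficients")


def _as_indexed(frame: pd.DataFrame, key: list[str]) -> pd.DataFrame:
    if list(frame.index.names) != key:
        frame = frame.set_index(key)
    return frame.sort_index()


# ---------------------------------------------------------------------------
# input bundle


@dataclass
class InputBundle:
    """Everything one pipeline run consumes.

    Gridded fields are xarray DataArrays: ``deposition`` with dims
    (time, lat, lon) in kg N ha-1 month-1, ``manure_grid`` with dims
    (year, lat, lon) in kg N ha-1 yr-1 (per NCA).
    """

    land_use: pd.DataFrame
    fertilizer: pd.DataFrame
    crops: pd.DataFrame
    livestock: pd.DataFrame
    deposition: "object"
    manure_grid: "object"
    coefficients: CoefficientSet
    centroids: pd.DataFrame
    region_mapping: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def years(self) -> list[int]:
        return sorted(self.land_use["year"].unique().tolist())

    @property
    def districts(self) -> list:
        return sorted(self.land_use["district_id"].unique().tolist())


# ---------------------------------------------------------------------------
# panel validation


@dataclass(frozen=True)
class Violation:
    table: str
    code: str
    message: str
    fatal: bool = True


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    def add(self, table: str, code: str, message: str, *, fatal: bool = True) -> None:
        self.violations.append(Violation(table, code, message, fatal))

    @property
    def fatal(self) -> list[Violation]:
        return [v for v in self.violations if v.fatal]

    @property
    def ok(self) -> bool:
        return not self.fatal

    def raise_if_fatal(self) -> None:
        if not self.ok:
            raise PanelValidationError(self)

    def __len__(self) -> int:
        return len(self.violations)


class PanelValidationError(ValueError):
    """Structured panel-validation failure carrying the first 50 violations."""

    def __init__(self, report: ValidationReport):
        self.report = report
        head = report.fatal[:50]
        lines = "\n".join(f"  [{v.table}/{v.code}] {v.message}" for v in head)
        more = len(report.fatal) - len(head)
        suffix = f"\n  ... and {more} more" if more > 0 else ""
        super().__init__(f"panel validation failed with {len(report.fatal)} fatal violations:\n{lines}{suffix}")


def _dup_keys(frame: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    return frame[frame.duplicated(subset=keys, keep=False)].drop_duplicates(subset=keys)


def validate_panel(
    land_use: pd.DataFrame,
    fertilizer: pd.DataFrame,
    crops: pd.DataFrame,
    livestock: pd.DataFrame,
    *,
    years: tuple[int, int] | None = None,
) -> ValidationReport:
    """Structural and sign checks on the four panel tables.

    ``years`` (start, end), when given, flags records outside the configured
    span.  The panel is acceptable iff the report has no fatal entry.
    """
    rep = ValidationReport()

    for name, frame, cols in (
        ("land_use", land_use, LAND_USE_COLUMNS),
        ("fertilizer", fertilizer, FERTILIZER_COLUMNS),
        ("crops", crops, CROP_COLUMNS),
        ("livestock", livestock, LIVESTOCK_COLUMNS),
    ):
        missing = set(cols) - set(frame.columns)
        if missing:
            rep.add(name, "schema", f"missing columns {sorted(missing)}")

    if rep.fatal:
        return rep

    for _, r in land_use.iterrows():
        key = f"district {r.district_id}, year {int(r.year)}"
        if r.net_cropped_area < 0 or r.gross_cropped_area < 0 or r.district_area < 0:
            rep.add("land_use", "negative area", f"{key}: negative area")
        elif r.gross_cropped_area < r.net_cropped_area:
            rep.add("land_use", "gca<nca", f"{key}: GCA {r.gross_cropped_area} < NCA {r.net_cropped_area}")
        if not 0 <= r.cropland_fraction <= 1:
            rep.add("land_use", "cropland fraction", f"{key}: cropland_fraction {r.cropland_fraction} outside [0, 1]")
        else:
            cropland = r.cropland_fraction * r.district_area
            if r.net_cropped_area > 0 and abs(cropland - r.net_cropped_area) > 0.05 * max(r.net_cropped_area, cropland):
                rep.add("land_use", "area consistency",
                        f"{key}: cropland {cropland:.1f} ha vs NCA {r.net_cropped_area:.1f} ha", fatal=False)

    for _, r in _dup_keys(land_use, ["district_id", "year"]).iterrows():
        rep.add("land_use", "duplicate key", f"duplicated (district {r.district_id}, year {int(r.year)})")

    if (fertilizer["total_n_applied"] < 0).any():
        n = int((fertilizer["total_n_applied"] < 0).sum())
        rep.add("fertilizer", "negative value", f"{n} records with negative total_n_applied")
    for _, r in _dup_keys(fertilizer, ["district_id", "year"]).iterrows():
        rep.add("fertilizer", "duplicate key", f"duplicated (district {r.district_id}, year {int(r.year)})")

    bad = crops[(crops["harvested_area"] < 0) | (crops["production"] < 0)]
    for _, r in bad.iterrows():
        rep.add("crops", "negative value", f"district {r.district_id}, year {int(r.year)}, crop {r.crop_id}: negative area/production")
    ghost = crops[(crops["harvested_area"] == 0) & (crops["production"] > 0)]
    for _, r in ghost.iterrows():
        rep.add("crops", "production without area", f"district {r.district_id}, year {int(r.year)}, crop {r.crop_id}: production with zero harvested area")
    for _, r in _dup_keys(crops, ["district_id", "year", "crop_id"]).iterrows():
        rep.add("crops", "duplicate key", f"duplicated (district {r.district_id}, year {int(r.year)}, crop {r.crop_id})")

    if (livestock["headcount"] < 0).any():
        n = int((livestock["headcount"] < 0).sum())
        rep.add("livestock", "negative value", f"{n} records with negative headcount")
    for _, r in _dup_keys(livestock, ["district_id", "census_year", "category_id"]).iterrows():
        rep.add("livestock", "duplicate key", f"duplicated (district {r.district_id}, census {int(r.census_year)}, {r.category_id})")
    if len(livestock):
        anchor = int(livestock["census_year"].min())
        off = livestock[(livestock["census_year"] - anchor) % CENSUS_INTERVAL != 0]
        for cy in sorted(off["census_year"].unique()):
            rep.add("livestock", "census grid", f"census year {int(cy)} off the {CENSUS_INTERVAL}-year grid anchored at {anchor}")

    if years is not None:
        lo, hi = years
        for name, frame, col in (("land_use", land_use, "year"), ("fertilizer", fertilizer, "year"),
                                 ("crops", crops, "year"), ("livestock", livestock, "census_year")):
            out = frame[(frame[col] < lo) | (frame[col] > hi)]
            for y in sorted(out[col].unique()):
                rep.add(name, "year span", f"year {int(y)} outside configured span {lo}-{hi}")

    return rep
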