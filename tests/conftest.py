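"""Shared fixtures: seeded synthetic bundles and hand-built micro-panels."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import nbudget as nb
from nbudget.core import CoefficientSet


@pytest.fixture(scope="session")
def tiny_bundle() -> nb.InputBundle:
    """5 districts, 1966-1980, fixed seed; fast enough for per-module tests."""
    return nb.generate_bundle(nb.ScenarioConfig(n_districts=5, n_states=2, end_year=1980, rng_seed=7))


@pytest.fixture(scope="session")
def default_bundle() -> nb.InputBundle:
    """The default 25-district, 1966-2017 scenario."""
    return nb.generate_bundle(nb.ScenarioConfig(rng_seed=11))


@pytest.fixture(scope="session")
def default_ensemble(default_bundle) -> nb.SurplusEnsemble:
    return nb.build_ensemble(default_bundle)


def make_land_use(
    districts=("D1",), years=(2000,), nca=100.0, gca=150.0, district_area=200.0, cropland_fraction=0.5
) -> pd.DataFrame:
    rows = [(d, y, nca, gca, district_area, cropland_fraction) for d in districts for y in years]
    return pd.DataFrame(rows, columns=list(nb.core.LAND_USE_COLUMNS))


def make_coefficients(
    *,
    bnf=None,
    n_content=None,
    manure=None,
    prosys_shares=None,
    policy="skip",
) -> CoefficientSet:
    """Single-crop / single-category coefficient set, overridable per table."""
    if bnf is None:
        bnf = pd.DataFrame([("c1", 0.0, 1.0, 1.0, 0.0)], columns=list(nb.core.BNF_COEF_COLUMNS))
    if n_content is None:
        n_content = pd.DataFrame(
            [("c1", "FAO", 0.02), ("c1", "BOUWMAN", 0.02)], columns=list(nb.core.N_CONTENT_COLUMNS)
        )
    if manure is None:
        manure = make_manure_coefs()
    kwargs = {} if prosys_shares is None else {"prosys_shares": prosys_shares}
    return CoefficientSet(bnf=bnf, n_content=n_content, manure=manure, policy=policy, **kwargs)


def make_manure_coefs(rows=None) -> pd.DataFrame:
    """Manure coefficient rows; default single 'cattle' category."""
    if rows is None:
        rows = [dict(category_id="cattle")]
    base = dict(
        n_rate=0.3, tam=500.0,
        f_mt_irrigated=0.5, f_mo_irrigated=0.1, f_loss_irrigated=0.3,
        f_mt_rainfed=0.5, f_mo_rainfed=0.1, f_loss_rainfed=0.3,
        am_cn=0.2, am_cl=0.1, am_fl=0.25,
    )
    return pd.DataFrame([{**base, **r} for r in rows])[list(nb.core.MANURE_COEF_COLUMNS)]


def degenerate_bundle(base: nb.InputBundle) -> nb.InputBundle:
    """Bundle on which all 12 members coincide (zero methodological spread)."""
    return nb.synth.collapsed_bundle(base)


def series_of(values: dict, name=None) -> pd.Series:
    """(district, year) -> value dict as a panel Series."""
    s = pd.Series(values)
    s.index.set_names(["district_id", "year"], inplace=True)
    return s
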