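"""Readers, writers, run configuration and the end-to-end pipeline driver.

All tabular interfaces are comma-separated UTF-8 text with a header row and
'.' decimals; numeric output is written at 6 significant digits so that
write -> read round-trips are stable.  Gridded fields travel as long-format
CSV (columns time|year, lat, lon, value) with a JSON sidecar carrying units
and the variable name; NetCDF3 files are also accepted where the optional
scipy engine can read them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import aggregate as agg_mod
from . import core, ensemble as ens_mod, synth, validate as val_mod

FLOAT_FORMAT = "%.6g"

KNOWN_GRID_UNITS = {
    "kg N ha-1 month-1": 1.0,
    "kg N ha-1 yr-1": 1.0,
}
SI_FLUX_UNITS = "kg m-2 s-1"

_TABLE_SCHEMAS = {
    "land_use": core.LAND_USE_COLUMNS,
    "fertilizer": core.FERTILIZER_COLUMNS,
    "crops": core.CROP_COLUMNS,
    "livestock": core.LIVESTOCK_COLUMNS,
    "bnf_coefficients": core.BNF_COEF_COLUMNS,
    "n_content": core.N_CONTENT_COLUMNS,
    "manure_coefficients": core.MANURE_COEF_COLUMNS,
    "centroids": core.CENTROID_COLUMNS,
    "region_mapping": core.MAPPING_COLUMNS,
}


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read one of the declared CSV schemas, checking required columns."""
    cols = _TABLE_SCHEMAS[kind]
    frame = pd.read_csv(path)
    missing = set(cols) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: {kind} table missing columns {sorted(missing)}")
    return frame[list(cols)]


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_component(series: core.ComponentSeries, path: str | Path) -> None:
    write_table(series.to_frame(), path)


# ---------------------------------------------------------------------------
# grids


def write_grid(grid: xr.DataArray, path: str | Path) -> None:
    """Long-format CSV plus a `.meta.json` sidecar (units, dims, name)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    time_dim = "time" if "time" in grid.dims else "year"
    long = grid.to_series().rename("value").reset_index()
    long.to_csv(path, index=False, float_format="%.10g")
    meta = {"name": grid.name, "units": grid.attrs.get("units"), "time_dim": time_dim}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_grid(path: str | Path) -> xr.DataArray:
    """Read a gridded field (long CSV + sidecar, or NetCDF3).

    Coordinates are sorted ascending.  Unknown or missing units raise;
    SI deposition fluxes (kg m-2 s-1) are converted to kg N ha-1 month-1
    at this boundary.
    """
    path = Path(path)
    if path.suffix == ".nc":
        da = xr.open_dataarray(path, engine="scipy")
        units = da.attrs.get("units")
    else:
        meta_path = Path(str(path) + ".meta.json")
        if not meta_path.exists():
            raise ValueError(f"{path}: missing sidecar {meta_path.name} with units metadata")
        meta = json.loads(meta_path.read_text())
        units = meta.get("units")
        time_dim = meta.get("time_dim", "time")
        long = pd.read_csv(path)
        if time_dim not in long.columns:
            raise ValueError(f"{path}: missing time dimension column {time_dim!r}")
        if time_dim == "time":
            long["time"] = pd.to_datetime(long["time"])
        da = long.set_index([time_dim, "lat", "lon"])["value"].to_xarray()
        da.name = meta.get("name")
        da.attrs["units"] = units
    if units is None or (units not in KNOWN_GRID_UNITS and units != SI_FLUX_UNITS):
        raise ValueError(f"{path}: unknown units attribute {units!r}; refusing to assume")
    da = da.sortby([d for d in da.dims])
    if units == SI_FLUX_UNITS:
        from . import deposition

        da = deposition.si_flux_to_monthly(da)
    return da


# ---------------------------------------------------------------------------
# bundles on disk


def write_bundle(bundle: core.InputBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(bundle.land_use, out / "land_use.csv")
    write_table(bundle.fertilizer, out / "fertilizer.csv")
    write_table(bundle.crops, out / "crops.csv")
    write_table(bundle.livestock, out / "livestock.csv")
    write_table(bundle.centroids, out / "centroids.csv")
    write_table(bundle.region_mapping, out / "region_mapping.csv")
    cf = bundle.coefficients
    write_table(cf.bnf.reset_index(), out / "bnf_coefficients.csv")
    write_table(cf.n_content.reset_index(), out / "n_content.csv")
    write_table(cf.manure.reset_index(), out / "manure_coefficients.csv")
    write_grid(bundle.deposition, out / "deposition.csv")
    write_grid(bundle.manure_grid, out / "manure_grid.csv")
    (out / "bundle_meta.json").write_text(json.dumps(
        {"prosys_shares": dict(cf.prosys_shares), "policy": cf.policy, **bundle.meta}, indent=1, default=str))


def read_bundle(in_dir: str | Path, *, policy: str = "skip") -> core.InputBundle:
    ind = Path(in_dir)
    for required in ("land_use", "fertilizer", "crops", "livestock"):
        if not (ind / f"{required}.csv").exists():
            raise FileNotFoundError(f"missing input table {ind / (required + '.csv')}")
    meta = {}
    shares = None
    meta_path = ind / "bundle_meta.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        shares = meta.get("prosys_shares")
        policy = meta.get("policy", policy)
    cf_kwargs = {} if shares is None else {"prosys_shares": shares}
    coefficients = core.CoefficientSet(
        bnf=read_table(ind / "bnf_coefficients.csv", "bnf_coefficients"),
        n_content=read_table(ind / "n_content.csv", "n_content"),
        manure=read_table(ind / "manure_coefficients.csv", "manure_coefficients"),
        policy=policy,
        **cf_kwargs,
    )
    return core.InputBundle(
        land_use=read_table(ind / "land_use.csv", "land_use"),
        fertilizer=read_table(ind / "fertilizer.csv", "fertilizer"),
        crops=read_table(ind / "crops.csv", "crops"),
        livestock=read_table(ind / "livestock.csv", "livestock"),
        deposition=read_grid(ind / "deposition.csv"),
        manure_grid=read_grid(ind / "manure_grid.csv"),
        coefficients=coefficients,
        centroids=read_table(ind / "centroids.csv", "centroids"),
        region_mapping=read_table(ind / "region_mapping.csv", "region_mapping"),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# run configuration and pipeline driver


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (YAML-serializable)."""

    input_dir: str
    output_dir: str
    basis: str = core.NET
    nhi_mode: str = "multiply"
    policy: str = "skip"
    through_year: int | None = None
    schemes: tuple = ("state", "basin", "subbasin", "national")
    cutoff_km: float | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        if not Path(cfg.input_dir).exists():
            raise FileNotFoundError(f"input directory {cfg.input_dir} does not exist")
        return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Validate, build the 12-member ensemble, aggregate, and write outputs.

    Writes one CSV per member, the district summary, per-scheme aggregate
    summaries, and a provenance JSON sufficient to re-execute the run.
    Re-running on identical inputs produces byte-identical outputs.
    """
    bundle = read_bundle(config.input_dir, policy=config.policy)
    report = core.validate_panel(bundle.land_use, bundle.fertilizer, bundle.crops, bundle.livestock)
    report.raise_if_fatal()
    for v in report.violations:
        warnings.warn(f"panel validation: [{v.table}/{v.code}] {v.message}", stacklevel=2)

    ens = ens_mod.build_ensemble(
        bundle, config.basis, nhi_mode=config.nhi_mode,
        through_year=config.through_year, cutoff_km=config.cutoff_km,
    )
    out = Path(config.output_dir)
    (out / "members").mkdir(parents=True, exist_ok=True)
    paths = {}
    for member_id in sorted(ens.members):
        frame = ens.members[member_id].rename("surplus_kgN_ha").reset_index()
        p = out / "members" / f"surplus_{member_id}.csv"
        write_table(frame, p)
        paths[member_id] = str(p)
    summary = ens_mod.summarize(ens)
    write_table(summary.reset_index(), out / "summary_district.csv")

    for scheme in config.schemes:
        _, ssum = agg_mod.aggregate_ensemble(ens, bundle.region_mapping, bundle.land_use, scheme)
        write_table(ssum.reset_index(), out / f"summary_{scheme}.csv")

    national = val_mod.national_series(ens, bundle.land_use, mode="per_ha")
    write_table(national.reset_index(), out / "national_per_ha.csv")

    from . import __version__

    provenance = {
        "package_version": __version__,
        "config": {**config.__dict__, "schemes": list(config.schemes)},
        "ensemble_meta": ens.meta,
        "n_districts": len(bundle.districts),
        "years": [min(bundle.years), max(bundle.years)],
        "validation_warnings": [f"[{v.table}/{v.code}] {v.message}" for v in report.violations],
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1, sort_keys=True, default=str))
    return {"members": paths, "output_dir": str(out), "ensemble": ens, "bundle": bundle}
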