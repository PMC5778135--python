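"""NetCDF/CSV/YAML serialization for every pipeline artifact.

Gridded fields travel as CF-style NetCDF (classic format via the scipy
backend): ascending ``lat``/``lon`` cell-centre coordinates, one data
variable per physical quantity with a mandatory ``units`` attribute, and
an ancillary ``land_mask`` variable.  Files written with descending
latitude elsewhere are re-oriented north-up on read.  Tables are UTF-8
CSV with a header row; configs are YAML; bundle manifests are JSON with
SHA-256 checksums.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .grid import GriddedField, GridSpec
from .synth import (
    AGE_BINS,
    DECADES,
    BaselineMortalityTable,
    ModelPentadRecord,
    ScenarioDrivers,
    SyntheticConfig,
)

_ENGINE = "scipy"  # classic NetCDF3; always available offline


class FormatError(ValueError):
    """A file violates the expected on-disk schema."""


def sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _grid_from_coords(lats: np.ndarray, lons: np.ndarray) -> GridSpec:
    res = float(np.round(lats[1] - lats[0], 9)) if len(lats) > 1 else 0.5
    return GridSpec(
        lat_min=float(lats[0] - res / 2), lat_max=float(lats[-1] + res / 2),
        lon_min=float(lons[0] - res / 2), lon_max=float(lons[-1] + res / 2),
        resolution=res,
    )


def _coords(grid: GridSpec) -> dict:
    return {"lat": ("lat", grid.lats, {"units": "degrees_north"}),
            "lon": ("lon", grid.lons, {"units": "degrees_east"})}


def write_gridded(field: GriddedField, path: str | Path, name: str = "value",
                  attrs: dict | None = None) -> None:
    ds = xr.Dataset(
        {
            name: (("lat", "lon"), field.values, {"units": field.units}),
            "land_mask": (("lat", "lon"), field.mask.astype(np.int8), {"units": "1"}),
        },
        coords=_coords(field.grid),
        attrs=attrs or {},
    )
    ds.to_netcdf(path, engine=_ENGINE)


def _normalize_latitude(ds: xr.Dataset) -> xr.Dataset:
    lats = ds["lat"].values
    diffs = np.diff(lats)
    if len(diffs) and np.all(diffs < 0):
        return ds.isel(lat=slice(None, None, -1))
    if len(diffs) and not np.all(diffs > 0):
        raise FormatError("latitude coordinate is not monotonic")
    return ds


def read_gridded(path: str | Path, name: str | None = None) -> GriddedField:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds = _normalize_latitude(ds.load())
        data_vars = [v for v in ds.data_vars if v != "land_mask"]
        if name is None:
            if len(data_vars) != 1:
                raise FormatError(f"expected one data variable, found {data_vars}")
            name = data_vars[0]
        if name not in ds:
            raise FormatError(f"variable {name!r} not found in {path}")
        var = ds[name]
        if "units" not in var.attrs:
            raise FormatError(f"variable {name!r} lacks the mandatory 'units' attribute")
        grid = _grid_from_coords(ds["lat"].values, ds["lon"].values)
        mask = (ds["land_mask"].values.astype(bool)
                if "land_mask" in ds else np.ones(grid.shape, dtype=bool))
        return GriddedField(var.values, str(var.attrs["units"]), mask, grid)


# ---------------------------------------------------------------------------
# ensemble and population bundles
# ---------------------------------------------------------------------------

def write_ensemble(records: list[ModelPentadRecord], path: str | Path) -> None:
    """One NetCDF per scenario: species and AOD stacked over (model, window).

    Species a member does not report are stored as NaN blocks and dropped
    on read, preserving the reporting gaps.
    """
    scenario = records[0].scenario
    models = sorted({r.model_id for r in records})
    windows = sorted({r.pentad for r in records})
    all_species = sorted({s for r in records for s in r.species})
    ref = records[0].species[next(iter(records[0].species))]
    grid, mask = ref.grid, ref.mask
    shape = (len(models), len(windows), *grid.shape)

    arrays = {sp: np.full(shape, np.nan) for sp in all_species}
    aod = np.full(shape, np.nan)
    index = {(r.model_id, r.pentad): r for r in records}
    for i, m in enumerate(models):
        for j, w in enumerate(windows):
            rec = index[(m, w)]
            for sp, fld in rec.species.items():
                arrays[sp][i, j] = fld.values
            aod[i, j] = rec.aod.values

    dims = ("model", "window", "lat", "lon")
    data = {sp: (dims, arrays[sp], {"units": "ug m-3"}) for sp in all_species}
    data["aod"] = (dims, aod, {"units": "1"})
    data["land_mask"] = (("lat", "lon"), mask.astype(np.int8), {"units": "1"})
    ds = xr.Dataset(
        data,
        coords={"model": models, "window": windows, **_coords(grid)},
        attrs={"scenario": scenario},
    )
    ds.to_netcdf(path, engine=_ENGINE)


def read_ensemble(path: str | Path) -> list[ModelPentadRecord]:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds = _normalize_latitude(ds.load())
        scenario = str(ds.attrs["scenario"])
        grid = _grid_from_coords(ds["lat"].values, ds["lon"].values)
        mask = ds["land_mask"].values.astype(bool)
        species_names = [v for v in ds.data_vars if v not in ("aod", "land_mask")]
        records = []
        for m in ds["model"].values:
            for w in ds["window"].values:
                sel = ds.sel(model=m, window=w)
                species = {}
                for sp in species_names:
                    vals = sel[sp].values
                    if np.isnan(vals).all():
                        continue
                    species[sp] = GriddedField(vals, "ug m-3", mask, grid)
                records.append(ModelPentadRecord(
                    str(m), scenario, str(w), species,
                    GriddedField(sel["aod"].values, "1", mask, grid),
                ))
        return records


def write_population(drivers: ScenarioDrivers, path: str | Path) -> None:
    decades = list(drivers.decades)
    first = drivers.population[decades[0]]
    stack = np.stack([drivers.population[d].values for d in decades])
    ds = xr.Dataset(
        {
            "population": (("decade", "lat", "lon"), stack, {"units": "persons"}),
            "land_mask": (("lat", "lon"), first.mask.astype(np.int8), {"units": "1"}),
        },
        coords={"decade": decades, **_coords(first.grid)},
        attrs={"ssp": drivers.ssp},
    )
    ds.to_netcdf(path, engine=_ENGINE)


def read_population(path: str | Path) -> tuple[str, dict]:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds = _normalize_latitude(ds.load())
        grid = _grid_from_coords(ds["lat"].values, ds["lon"].values)
        mask = ds["land_mask"].values.astype(bool)
        pop = {
            str(d): GriddedField(ds["population"].sel(decade=d).values, "persons", mask, grid)
            for d in ds["decade"].values
        }
        return str(ds.attrs["ssp"]), pop


def write_projection(proj, path: str | Path) -> None:
    """One NetCDF per scenario x approach: pentad and decade summaries."""
    from .exposure import ExposureProjection  # noqa: F401  (type reference)

    pentads = list(proj.pentads)
    decades = list(proj.decades)
    first = proj.mean[pentads[0]]
    grid, mask = first.grid, first.mask

    def stack(d, keys):
        return np.stack([d[k].values for k in keys])

    ds = xr.Dataset(
        {
            "pentad_mean": (("pentad", "lat", "lon"), stack(proj.mean, pentads), {"units": "ug m-3"}),
            "pentad_sigma": (("pentad", "lat", "lon"), stack(proj.sigma, pentads), {"units": "ug m-3"}),
            "decade_mean": (("decade", "lat", "lon"), stack(proj.decade_mean, decades), {"units": "ug m-3"}),
            "decade_sigma": (("decade", "lat", "lon"), stack(proj.decade_sigma, decades), {"units": "ug m-3"}),
            "land_mask": (("lat", "lon"), mask.astype(np.int8), {"units": "1"}),
        },
        coords={"pentad": pentads, "decade": decades, **_coords(grid)},
        attrs={"scenario": proj.scenario, "approach": proj.approach},
    )
    ds.to_netcdf(path, engine=_ENGINE)


def read_projection(path: str | Path):
    from .exposure import ExposureProjection

    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds = _normalize_latitude(ds.load())
        grid = _grid_from_coords(ds["lat"].values, ds["lon"].values)
        mask = ds["land_mask"].values.astype(bool)

        def unstack(var, keys):
            return {str(k): GriddedField(ds[var].sel({ds[var].dims[0]: k}).values,
                                         "ug m-3", mask, grid) for k in keys}

        pentads = tuple(str(p) for p in ds["pentad"].values)
        decades = tuple(str(d) for d in ds["decade"].values)
        proj = ExposureProjection(
            scenario=str(ds.attrs["scenario"]), approach=str(ds.attrs["approach"]),
            pentads=pentads, member_pentad={},
        )
        proj.mean = unstack("pentad_mean", pentads)
        proj.sigma = unstack("pentad_sigma", pentads)
        proj.decade_mean = unstack("decade_mean", decades)
        proj.decade_sigma = unstack("decade_sigma", decades)
        return proj


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_age_fractions(path: str | Path) -> dict[str, pd.DataFrame]:
    """Per-SSP (decade x age-bin) fraction tables, validated to sum to 1."""
    raw = pd.read_csv(path)
    out = {}
    for ssp, sub in raw.groupby("ssp"):
        frame = sub.set_index("decade")[list(AGE_BINS)]
        sums = frame.sum(axis=1)
        bad = sums[(sums - 1.0).abs() > 1e-9]
        if not bad.empty:
            raise FormatError(
                f"age fractions for ssp={ssp} do not sum to 1 in decade(s) {list(bad.index)}"
            )
        out[str(ssp)] = frame
    return out


def read_gdp(path: str | Path) -> dict[str, tuple[pd.DataFrame, float]]:
    raw = pd.read_csv(path)
    out = {}
    for ssp, sub in raw.groupby("ssp"):
        frame = sub.set_index("decade")[["iiasa", "oecd"]]
        ref = float(sub["gdp_ppp_ref"].iloc[0])
        if ref <= 0:
            raise FormatError(f"non-positive GDP-PPP reference for ssp={ssp}")
        out[str(ssp)] = (frame, ref)
    return out


def read_mortality_table(path: str | Path, zones_k: int | None = None) -> BaselineMortalityTable:
    frame = pd.read_csv(path)
    required = {"zone", "disease", "rate", "a", "b", "se_a", "se_b", "zone_gdp"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"mortality table missing column(s) {sorted(missing)}")
    bad = frame[(frame["rate"] < 0) | (frame["b"] < 0) | (frame["a"] < 0)]
    if not bad.empty:
        raise FormatError(f"negative mortality coefficients in rows {bad.index.tolist()}")
    if zones_k is None:
        zones_k = int(np.sqrt(frame["zone"].nunique()))
    return BaselineMortalityTable(frame, zones_k)


def load_drivers(bundle_dir: str | Path, ssp: str) -> ScenarioDrivers:
    """Reassemble one SSP's drivers from a fixture bundle on disk."""
    bundle = Path(bundle_dir)
    ssp_read, pop = read_population(bundle / f"population_{ssp}.nc")
    if ssp_read != ssp:
        raise FormatError(f"population file claims ssp={ssp_read}, expected {ssp}")
    ages = read_age_fractions(bundle / "age_fractions.csv")[ssp]
    gdp, ref = read_gdp(bundle / "gdp_ppp.csv")[ssp]
    return ScenarioDrivers(ssp, tuple(DECADES), pop, ages, gdp, ref)


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def write_config(config: SyntheticConfig, path: str | Path) -> None:
    import json

    doc = {"config_hash": config.config_hash(), **config.to_dict()}
    doc = json.loads(json.dumps(doc, default=float))  # strip numpy scalar types
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_config(path: str | Path) -> SyntheticConfig:
    doc = yaml.safe_load(Path(path).read_text())
    doc.pop("config_hash", None)
    return SyntheticConfig.from_dict(doc)
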