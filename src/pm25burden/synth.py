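"""Seeded generator of every input the projection pipeline consumes.

The generator emulates the statistical structure of the real study inputs
without touching any archive:

* a spatially heterogeneous satellite-style baseline PM2.5 field with a
  high-exposure hotspot (an Indo-Gangetic-basin analogue) whose national
  land mean hits a configured target;
* AOD consistent with a smooth, strictly positive per-grid conversion
  factor eta = PM2.5/AOD (kept for test oracles);
* a 13-member climate-model ensemble whose members share a per-scenario
  emission trend and meteorology modifier, with member-specific lognormal
  bias and noise, species-resolved so the species-sum estimation path can
  be exercised (including the POA/SOA reporting gaps);
* SSP-shaped national population curves (exactly one monotone analogue),
  a fixed settlement field for gridded allocation, ageing national age
  fractions, rising GDP-PPP trajectories, and a GDP-anchored baseline
  mortality table for four diseases.

Everything is a pure function of (seed, config): identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grid import ConfigurationError, GriddedField, GridSpec, elliptical_land_mask, zone_ids

# ---------------------------------------------------------------------------
# calendars
# ---------------------------------------------------------------------------

PENTADS: tuple[str, ...] = tuple(
    f"{y}-{y + 4}" for y in range(2011, 2100, 5)
)  # 2011-2015 ... 2096-2100, 18 windows
DECADES: tuple[str, ...] = tuple(f"{y}-{y + 9}" for y in range(2011, 2100, 10))  # 9 windows
BASELINE_WINDOW = "2001-2005"

#: decade label -> the two constituent pentad labels
DECADE_PENTADS: dict[str, tuple[str, str]] = {
    d: (PENTADS[2 * i], PENTADS[2 * i + 1]) for i, d in enumerate(DECADES)
}

SCENARIOS = ("rcp45", "rcp85")
SSPS = ("ssp1", "ssp2", "ssp3", "ssp4", "ssp5")

DISEASES = ("COPD", "IHD", "stroke", "LC")
AGE_SPECIFIC_DISEASES = ("IHD", "stroke")

#: 5-year adult age bins, 25-29 ... 80+
AGE_BINS: tuple[str, ...] = tuple(f"{a}-{a + 4}" for a in range(25, 80, 5)) + ("80+",)

# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

# Per-pentad national multiplicative emission trend on baseline PM2.5.
# The stabilisation analogue peaks in the 2020s and falls below baseline
# mid-century; the high-emission analogue peaks around 2040 and drops
# below baseline only at the very end of the century.
_TREND_RCP45 = [1.12, 1.20, 1.26, 1.28, 1.26, 1.22, 1.18, 1.14, 1.02,
                0.92, 0.84, 0.76, 0.69, 0.62, 0.56, 0.51, 0.47, 0.44]
_TREND_RCP85 = [1.15, 1.25, 1.33, 1.40, 1.45, 1.48, 1.44, 1.38, 1.31,
                1.25, 1.19, 1.13, 1.08, 1.04, 1.02, 1.00, 0.97, 0.94]

# Fractional meteorology modifier applied only in species-sum mode.
# Negative = suppression (washout/dispersion averts exposure).  The
# stabilisation analogue suppresses ~7% early growing to ~17% late; the
# high-emission analogue suppresses slightly early, enhances mid-century,
# and turns weakly favourable again in the last decade.
_MET_RCP45 = [round(float(x), 6) for x in np.linspace(-0.07, -0.17, len(PENTADS))]
_MET_RCP85 = [-0.030, -0.030, -0.035, -0.040, -0.040, -0.040, -0.020, 0.000,
              0.020, 0.030, 0.030, 0.040, 0.040, 0.030, 0.020, 0.010, -0.010, -0.020]

# National adult (>25 y) population totals (persons) in the first year of
# each decade.  Exactly one pathway (the ssp3 analogue) is monotone
# non-decreasing; the others peak strictly before the final decade.
_POP = {
    "ssp1": [0.68, 0.76, 0.83, 0.88, 0.90, 0.88, 0.84, 0.78, 0.72],
    "ssp2": [0.68, 0.77, 0.85, 0.92, 0.97, 0.99, 0.98, 0.95, 0.91],
    "ssp3": [0.68, 0.78, 0.89, 1.00, 1.11, 1.21, 1.30, 1.38, 1.45],
    "ssp4": [0.68, 0.76, 0.84, 0.90, 0.94, 0.95, 0.93, 0.90, 0.85],
    "ssp5": [0.68, 0.75, 0.82, 0.86, 0.87, 0.85, 0.80, 0.74, 0.68],
}
_POP_SCALE = 1.0e9  # adults

# Cumulative GDP-PPP growth multipliers relative to the 2010 reference,
# per decade.  Strictly increasing everywhere; fastest growth for the
# ssp5 analogue, slowest for ssp3.
_GDP_GROWTH = {
    "ssp1": [1.03, 1.70, 2.70, 4.00, 5.50, 7.20, 9.00, 10.80, 12.50],
    "ssp2": [1.02, 1.60, 2.40, 3.40, 4.50, 5.70, 6.90, 8.00, 9.00],
    "ssp3": [1.00, 1.40, 1.85, 2.30, 2.75, 3.15, 3.50, 3.80, 4.05],
    "ssp4": [1.01, 1.50, 2.15, 2.90, 3.70, 4.50, 5.30, 6.00, 6.60],
    "ssp5": [1.05, 1.85, 3.10, 4.80, 6.90, 9.40, 12.20, 15.20, 18.30],
}
_GDP_PPP_REF_2010 = 10.0  # arbitrary PPP units; kept > 1 so power laws are tame
_GDP_BASE_CONSTANT = 10.0  # national constant-price GDP in the baseline period

# Disease-specific baseline mortality among adults >25 y (deaths per
# person per year at national baseline GDP) and the exponent of the
# declining power law y = a * GDP^(-b).  LC is GDP-invariant (b = 0).
_MORTALITY = {
    # disease: (national baseline rate, b, relative SE on a, relative SE on b)
    "COPD": (0.0012, 0.45, 0.10, 0.12),
    "IHD": (0.0022, 0.35, 0.10, 0.12),
    "stroke": (0.0011, 0.40, 0.10, 0.12),
    "LC": (0.00015, 0.0, 0.10, 0.0),
}

# Species mass shares of member PM2.5 used to synthesise per-species
# concentration fields.  Shares are chosen so the species-sum estimator
# (BC + OA + SO4 + NH4 + 0.25*SS + 0.1*dust, NH4 = 36*SO4/96)
# reconstructs the member PM2.5 exactly.
_F_BC = 0.08
_F_OA = 0.27
_F_SO4_PLUS_NH4 = 0.45
_F_SS_CONTRIB = 0.10   # stored SS field = 4x this (0.25 weight)
_F_DUST_CONTRIB = 0.10  # stored dust field = 10x this (0.1 weight)
_POA_SHARE_OF_OA = 0.6  # SOA share is the complement


@dataclass
class HotspotSpec:
    """Centre/extent/strength of the planted high-exposure sub-region."""

    lat: float = 26.5
    lon: float = 82.0
    radius_deg: float = 4.0
    amplitude: float = 30.0  # additive peak excess, ug m-3


@dataclass
class SyntheticConfig:
    """Full description of one synthetic study; see module docstring."""

    seed: int = 0
    grid: GridSpec = field(default_factory=GridSpec)
    n_models: int = 13
    pentads: tuple[str, ...] = PENTADS
    baseline_window: str = BASELINE_WINDOW
    scenario_trends: dict = field(
        default_factory=lambda: {"rcp45": list(_TREND_RCP45), "rcp85": list(_TREND_RCP85)}
    )
    meteorology_effect: dict = field(
        default_factory=lambda: {"rcp45": list(_MET_RCP45), "rcp85": list(_MET_RCP85)}
    )
    noise_sd: float = 0.08     # per-(member, pentad) multiplicative log-noise
    bias_sd: float = 0.30      # fixed per-member multiplicative log-bias
    noise_length_scale: float = 3.0  # cells; Gaussian smoothing of noise fields
    hotspot: HotspotSpec = field(default_factory=HotspotSpec)
    national_mean_pm25: float = 34.5  # ug m-3, baseline land mean target
    eta_range: tuple[float, float] = (35.0, 65.0)  # ug m-3 per unit AOD
    zones_k: int = 4
    ssp_population: dict = field(default_factory=lambda: {k: list(v) for k, v in _POP.items()})
    population_scale: float = _POP_SCALE
    gdp_growth: dict = field(default_factory=lambda: {k: list(v) for k, v in _GDP_GROWTH.items()})
    gdp_ppp_ref: float = _GDP_PPP_REF_2010
    gdp_base: float = _GDP_BASE_CONSTANT
    mortality_coeff: dict = field(default_factory=lambda: {k: tuple(v) for k, v in _MORTALITY.items()})
    ageing_rates: tuple[float, float] = (0.78, 0.92)  # geometric age-profile ratio, first->last decade

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = dataclasses.asdict(self.grid)
        d["hotspot"] = dataclasses.asdict(self.hotspot)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "grid" in d:
            d["grid"] = GridSpec(**d["grid"])
        if "hotspot" in d:
            d["hotspot"] = HotspotSpec(**d["hotspot"])
        if "pentads" in d:
            d["pentads"] = tuple(d["pentads"])
        for key in ("eta_range", "ageing_rates"):
            if key in d:
                d[key] = tuple(d[key])
        if "mortality_coeff" in d:
            d["mortality_coeff"] = {k: tuple(v) for k, v in d["mortality_coeff"].items()}
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# internal helpers
# ---------------------------------------------------------------------------

def _rng(config: SyntheticConfig, *stream: int) -> np.random.Generator:
    # independent, order-insensitive substreams keyed on (seed, stream ids)
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, *stream])


def _smooth_unit_field(rng: np.random.Generator, shape: tuple[int, int], length: float) -> np.ndarray:
    """Spatially correlated standard-normal field, clipped to +/-2.5."""
    white = rng.standard_normal(shape)
    sm = gaussian_filter(white, sigma=length, mode="nearest")
    sd = sm.std()
    if sd <= 0:
        return np.zeros(shape)
    return np.clip(sm / sd, -2.5, 2.5)


@dataclass
class BaselineFields:
    """Satellite-era baseline rasters plus the true conversion factor.

    ``eta_true`` is the generator's planted PM2.5/AOD ratio, retained so
    tests can compare the recomputed conversion factor against truth.
    """

    pm25: GriddedField
    aod: GriddedField
    eta_true: GriddedField

    def __iter__(self):  # allow (pm, aod) tuple-unpacking per the interface
        return iter((self.pm25, self.aod))


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_baseline_fields(config: SyntheticConfig) -> BaselineFields:
    """Baseline-period (2001-2005 analogue) PM2.5 and AOD rasters.

    The PM2.5 field is a smooth positive background plus a Gaussian
    hotspot bump of the configured amplitude; the background is scaled so
    the area-weighted land mean equals ``national_mean_pm25`` exactly.
    AOD = PM2.5 / eta_true with a smooth strictly positive eta_true.
    """
    grid = config.grid
    mask = elliptical_land_mask(grid)
    rng = _rng(config, 1)

    background = np.exp(0.25 * _smooth_unit_field(rng, grid.shape, config.noise_length_scale))

    la, lo = np.meshgrid(grid.lats, grid.lons, indexing="ij")
    hs = config.hotspot
    d2 = (la - hs.lat) ** 2 + (lo - hs.lon) ** 2
    bump = hs.amplitude * np.exp(-0.5 * d2 / hs.radius_deg**2)

    bg_field = GriddedField(background, "1", mask, grid)
    bump_mean = GriddedField(bump, "ug m-3", mask, grid).land_mean()
    scale = (config.national_mean_pm25 - bump_mean) / bg_field.land_mean()
    if scale <= 0:
        raise ConfigurationError("hotspot amplitude too large for the national mean target")
    pm_values = scale * background + bump
    pm25 = GriddedField(pm_values, "ug m-3", mask, grid)

    lo_eta, hi_eta = config.eta_range
    if lo_eta <= 0:
        raise ConfigurationError("eta range must be strictly positive")
    eta_shape = _smooth_unit_field(_rng(config, 2), grid.shape, config.noise_length_scale)
    eta_values = lo_eta + (hi_eta - lo_eta) * (eta_shape - eta_shape.min()) / np.ptp(eta_shape) \
        if np.ptp(eta_shape) > 0 else np.full(grid.shape, 0.5 * (lo_eta + hi_eta))
    eta_true = GriddedField(eta_values, "ug m-3", mask, grid)

    aod = GriddedField(pm_values / eta_values, "1", mask, grid)
    return BaselineFields(pm25=pm25, aod=aod, eta_true=eta_true)


@dataclass
class ModelPentadRecord:
    """One ensemble member's species + AOD fields for one time window."""

    model_id: str
    scenario: str
    pentad: str  # a pentad label or the baseline window label
    species: dict  # name -> GriddedField; subset allowed per reporting gaps
    aod: GriddedField

    @property
    def is_baseline(self) -> bool:
        return "-" in self.pentad and self.pentad.startswith("200")


def _species_split(pm: np.ndarray, model_index: int, mask: np.ndarray, grid: GridSpec) -> dict:
    """Split member PM2.5 into reported species fields.

    Member 1 (index 0) is the reference and reports both POA and SOA;
    members 2-3 report only POA, members 4-5 only SOA, the rest total OA.
    """
    f = lambda arr: GriddedField(arr, "ug m-3", mask, grid)
    so4 = _F_SO4_PLUS_NH4 / (1.0 + 36.0 / 96.0) * pm
    out = {
        "BC": f(_F_BC * pm),
        "SO4": f(so4),
        "SS": f(_F_SS_CONTRIB / 0.25 * pm),
        "dust": f(_F_DUST_CONTRIB / 0.1 * pm),
    }
    oa = _F_OA * pm
    if model_index == 0:
        out["POA"] = f(_POA_SHARE_OF_OA * oa)
        out["SOA"] = f((1.0 - _POA_SHARE_OF_OA) * oa)
    elif model_index in (1, 2):
        out["POA"] = f(_POA_SHARE_OF_OA * oa)
    elif model_index in (3, 4):
        out["SOA"] = f((1.0 - _POA_SHARE_OF_OA) * oa)
    else:
        out["OA"] = f(oa)
    return out


def generate_model_ensemble(config: SyntheticConfig, scenario: str) -> list[ModelPentadRecord]:
    """Ensemble member records for every pentad plus a baseline record each.

    Member m's species-sum PM2.5 for pentad t is
    ``baseline * trend[t] * (1 + met[t]) * bias_m * noise_{m,t}`` and its
    AOD is ``baseline_aod * trend[t] * bias_m * noise_{m,t}`` — the AOD
    path carries the emission signal but not the meteorology term, which
    is exactly the approach-1 vs approach-2 divergence the pipeline is
    meant to isolate.  The fixed member bias cancels in relative changes.
    """
    if scenario not in config.scenario_trends:
        raise ConfigurationError(
            f"unknown scenario {scenario!r}; configured: {sorted(config.scenario_trends)}"
        )
    trends = config.scenario_trends[scenario]
    mets = config.meteorology_effect.get(scenario, [0.0] * len(config.pentads))
    if len(trends) != len(config.pentads) or len(mets) != len(config.pentads):
        raise ConfigurationError("scenario trend/meteorology length must match the pentad calendar")

    base = generate_baseline_fields(config)
    grid, mask = config.grid, base.pm25.mask
    scen_id = SCENARIOS.index(scenario) if scenario in SCENARIOS else 7

    records: list[ModelPentadRecord] = []
    for m in range(config.n_models):
        model_id = f"model{m + 1:02d}"
        bias = np.exp(config.bias_sd * _smooth_unit_field(_rng(config, 10, m), grid.shape,
                                                          config.noise_length_scale))
        bl_pm = base.pm25.values * bias
        bl_aod = base.aod.values * bias
        records.append(ModelPentadRecord(
            model_id, scenario, config.baseline_window,
            _species_split(bl_pm, m, mask, grid),
            GriddedField(bl_aod, "1", mask, grid),
        ))
        for t, pentad in enumerate(config.pentads):
            if config.noise_sd > 0:
                noise = np.exp(config.noise_sd * _smooth_unit_field(
                    _rng(config, 20, scen_id, m, t), grid.shape, config.noise_length_scale))
            else:
                noise = 1.0
            pm = bl_pm * trends[t] * (1.0 + mets[t]) * noise
            aod = bl_aod * trends[t] * noise
            records.append(ModelPentadRecord(
                model_id, scenario, pentad,
                _species_split(pm, m, mask, grid),
                GriddedField(aod, "1", mask, grid),
            ))
    return records


@dataclass
class ScenarioDrivers:
    """One SSP analogue's demographic and economic drivers."""

    ssp: str
    decades: tuple[str, ...]
    population: dict  # decade -> GriddedField of adult persons
    age_fractions: pd.DataFrame  # index decade, columns AGE_BINS, rows sum to 1
    gdp_ppp: pd.DataFrame  # index decade, columns ["iiasa", "oecd"]
    gdp_ppp_ref: float  # world-bank-style 2010 reference

    def national_population(self, decade: str) -> float:
        return self.population[decade].land_sum()

    def gdp_growth(self, decade: str) -> float:
        row = self.gdp_ppp.loc[decade]
        g = 0.5 * (row["iiasa"] + row["oecd"]) / self.gdp_ppp_ref
        if g <= 0:
            raise ConfigurationError(f"non-positive GDP growth factor for {decade}")
        return float(g)


def settlement_field(config: SyntheticConfig) -> GriddedField:
    """Fixed settlement-weight raster used for population allocation.

    Shares are SSP- and decade-invariant; population moves only through
    the national totals, mirroring a static downscaling pattern.
    """
    grid = config.grid
    mask = elliptical_land_mask(grid)
    w = np.exp(0.5 * _smooth_unit_field(_rng(config, 3), grid.shape, config.noise_length_scale))
    w = np.where(mask, w, 0.0)
    return GriddedField(w, "1", mask, grid)


def _age_fraction_table(config: SyntheticConfig, decades: tuple[str, ...]) -> pd.DataFrame:
    r0, r1 = config.ageing_rates
    rows = {}
    nd = max(len(decades) - 1, 1)
    for i, dec in enumerate(decades):
        r = r0 + (r1 - r0) * i / nd  # ratio drifts up => mass shifts to older bins
        w = r ** np.arange(len(AGE_BINS))
        rows[dec] = w / w.sum()
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(AGE_BINS))


def generate_scenario_drivers(config: SyntheticConfig, ssp: str) -> ScenarioDrivers:
    if ssp not in config.ssp_population:
        raise ConfigurationError(f"unknown SSP {ssp!r}; configured: {sorted(config.ssp_population)}")
    totals = [t * config.population_scale for t in config.ssp_population[ssp]]
    if len(totals) != len(DECADES):
        raise ConfigurationError("population trajectory must have one total per decade")
    settle = settlement_field(config)
    shares = settle.values / settle.values.sum()

    population = {
        dec: GriddedField(totals[i] * shares, "persons", settle.mask, config.grid)
        for i, dec in enumerate(DECADES)
    }
    ages = _age_fraction_table(config, DECADES)

    growth = config.gdp_growth[ssp]
    if len(growth) != len(DECADES):
        raise ConfigurationError("gdp_growth must have one multiplier per decade")
    # the IIASA-like and OECD-like trajectories straddle the common growth curve
    gdp = pd.DataFrame(
        {
            "iiasa": [g * config.gdp_ppp_ref * 1.05 for g in growth],
            "oecd": [g * config.gdp_ppp_ref * 0.95 for g in growth],
        },
        index=list(DECADES),
    )
    return ScenarioDrivers(ssp, DECADES, population, ages, gdp, config.gdp_ppp_ref)


@dataclass
class BaselineMortalityTable:
    """Per-zone, per-disease baseline rates and the GDP decline curve.

    Rates follow y = a * GDP^(-b) with the LC rate GDP-invariant (b = 0);
    ``rate`` is the value at the zone's baseline GDP, so a = rate * GDP^b.
    """

    table: pd.DataFrame  # columns: zone, disease, rate, a, b, se_a, se_b, zone_gdp
    zones_k: int

    def zone_gdp(self, zone: int) -> float:
        sub = self.table[self.table["zone"] == zone]
        if sub.empty:
            raise KeyError(f"unknown zone {zone}")
        return float(sub["zone_gdp"].iloc[0])

    def coefficients(self, zone: int, disease: str) -> pd.Series:
        sub = self.table[(self.table["zone"] == zone) & (self.table["disease"] == disease)]
        if sub.empty:
            raise KeyError(f"no mortality coefficients for zone {zone}, disease {disease!r}")
        return sub.iloc[0]


def generate_baseline_mortality(config: SyntheticConfig) -> BaselineMortalityTable:
    for disease in DISEASES:
        if disease not in config.mortality_coeff:
            raise ConfigurationError(f"mortality_coeff missing disease {disease!r}")
    k = config.zones_k
    rng = _rng(config, 4)
    # baseline constant-price GDP per zone, spread +/-30% around national
    zone_gdp = config.gdp_base * (0.7 + 0.6 * rng.random(k * k))
    rows = []
    for z in range(k * k):
        for disease in DISEASES:
            rate_nat, b, rel_se_a, rel_se_b = config.mortality_coeff[disease]
            a = rate_nat * config.gdp_base**b  # anchor the national curve
            rate = a * zone_gdp[z] ** (-b)
            rows.append({
                "zone": z, "disease": disease, "rate": rate,
                "a": a, "b": b,
                "se_a": rel_se_a * a, "se_b": rel_se_b * b,
                "zone_gdp": zone_gdp[z],
            })
    return BaselineMortalityTable(pd.DataFrame(rows), k)


def zone_map(config: SyntheticConfig) -> np.ndarray:
    mask = elliptical_land_mask(config.grid)
    return zone_ids(config.grid, mask, config.zones_k)


# ---------------------------------------------------------------------------
# fixture bundle on disk
# ---------------------------------------------------------------------------

def write_fixture_bundle(config: SyntheticConfig, out_dir: str | Path) -> dict:
    """Serialize every generated input under ``out_dir``; return a manifest.

    Layout: baseline NetCDFs, one ensemble NetCDF per scenario, one
    population NetCDF per SSP, CSV tables, the YAML config and a JSON
    manifest with per-file SHA-256 checksums.
    """
    from . import io as _io  # local import to avoid a cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    base = generate_baseline_fields(config)
    for name, fld in (("baseline_pm25", base.pm25), ("baseline_aod", base.aod),
                      ("eta_true", base.eta_true)):
        p = out / f"{name}.nc"
        _io.write_gridded(fld, p, name=name)
        files[p.name] = _io.sha256_file(p)

    for scenario in config.scenario_trends:
        records = generate_model_ensemble(config, scenario)
        p = out / f"ensemble_{scenario}.nc"
        _io.write_ensemble(records, p)
        files[p.name] = _io.sha256_file(p)

    age_frames, gdp_frames = [], []
    for ssp in config.ssp_population:
        drivers = generate_scenario_drivers(config, ssp)
        p = out / f"population_{ssp}.nc"
        _io.write_population(drivers, p)
        files[p.name] = _io.sha256_file(p)
        af = drivers.age_fractions.copy()
        af.insert(0, "ssp", ssp)
        age_frames.append(af.reset_index(names="decade"))
        g = drivers.gdp_ppp.copy()
        g.insert(0, "ssp", ssp)
        g["gdp_ppp_ref"] = drivers.gdp_ppp_ref
        gdp_frames.append(g.reset_index(names="decade"))

    for fname, frame in (("age_fractions.csv", pd.concat(age_frames, ignore_index=True)),
                         ("gdp_ppp.csv", pd.concat(gdp_frames, ignore_index=True)),
                         ("baseline_mortality.csv", generate_baseline_mortality(config).table)):
        p = out / fname
        frame.to_csv(p, index=False)
        files[p.name] = _io.sha256_file(p)

    cfg_path = out / "config.yaml"
    _io.write_config(config, cfg_path)
    files[cfg_path.name] = _io.sha256_file(cfg_path)

    manifest = {
        "seed": int(config.seed),
        "config_hash": config.config_hash(),
        "n_models": config.n_models,
        "scenarios": sorted(config.scenario_trends),
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
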