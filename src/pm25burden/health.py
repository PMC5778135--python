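"""Attributable premature mortality from decadal PM2.5 exposure.

The exposure-response model is the integrated exposure-response (IER)
function

    RR(C) = 1 + alpha * (1 - exp(-gamma * dC**delta)),   dC = max(C - C0, 0)

with counterfactual concentration C0 (default 5.8 ug m-3) below which no
excess risk is assigned.  Four diseases are carried: COPD, IHD, stroke
and lung cancer (LC); IHD and stroke use one coefficient triple per
5-year adult age bin.  Attributable deaths follow the classical
population-attributable-fraction relation

    dM = y * (RR - 1)/RR * P

per grid cell, with the baseline mortality rate y inherited from the
cell's state ("zone") and declining with projected GDP as a power law
y = a * GDP^(-b) (LC is held GDP-invariant).  Uncertainty bands evaluate
the whole chain at ensemble-mean -/+ 1 sigma exposure jointly with the
mortality-curve coefficients shifted by -/+ 1 standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GriddedField, zone_ids
from .synth import (
    AGE_BINS,
    AGE_SPECIFIC_DISEASES,
    DISEASES,
    BaselineMortalityTable,
    ScenarioDrivers,
)

DEFAULT_COUNTERFACTUAL = 5.8  # ug m-3


@dataclass
class IERCoefficients:
    """Per-disease (alpha, gamma, delta) triples defining the RR curves.

    ``triples`` maps (disease, age_bin-or-None) to the coefficient
    triple.  COPD and LC carry exactly one triple (age_bin None); IHD
    and stroke carry one per adult age bin.
    """

    triples: dict
    counterfactual: float = DEFAULT_COUNTERFACTUAL

    def __post_init__(self) -> None:
        if self.counterfactual < 0:
            raise ValueError("counterfactual concentration must be >= 0")
        for key, (a, g, d) in self.triples.items():
            if a <= 0 or g <= 0 or d <= 0:
                raise ValueError(f"non-positive IER coefficient for {key}: {(a, g, d)}")
        for disease in AGE_SPECIFIC_DISEASES:
            for age_bin in AGE_BINS:
                if (disease, age_bin) not in self.triples:
                    raise ValueError(f"{disease} missing coefficient triple for age bin {age_bin}")
        for disease in set(DISEASES) - set(AGE_SPECIFIC_DISEASES):
            if (disease, None) not in self.triples:
                raise ValueError(f"{disease} missing its coefficient triple")

    @property
    def diseases(self) -> tuple[str, ...]:
        return DISEASES

    def triple(self, disease: str, age_bin: str | None = None) -> tuple[float, float, float]:
        if disease in AGE_SPECIFIC_DISEASES:
            if age_bin is None:
                raise ValueError(f"{disease} relative risk is age-specific; age_bin required")
            return self.triples[(disease, age_bin)]
        return self.triples[(disease, None)]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, counterfactual: float = DEFAULT_COUNTERFACTUAL) -> "IERCoefficients":
        triples = {}
        for _, row in frame.iterrows():
            age = row.get("age_bin")
            age = None if (pd.isna(age) or age == "") else str(age)
            triples[(str(row["disease"]), age)] = (
                float(row["alpha"]), float(row["gamma"]), float(row["delta"]))
        return cls(triples, counterfactual)

    @classmethod
    def from_csv(cls, path: str | Path, counterfactual: float = DEFAULT_COUNTERFACTUAL) -> "IERCoefficients":
        return cls.from_frame(pd.read_csv(path), counterfactual)

    @classmethod
    def default(cls) -> "IERCoefficients":
        """Illustrative, non-authoritative coefficient set shipped with the package."""
        with resources.files("pm25burden.data").joinpath("ier_coefficients_synthetic.csv").open() as fh:
            return cls.from_frame(pd.read_csv(fh))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"disease": dz, "age_bin": "" if ab is None else ab,
             "alpha": a, "gamma": g, "delta": d}
            for (dz, ab), (a, g, d) in sorted(self.triples.items(), key=lambda kv: (kv[0][0], kv[0][1] or ""))
        ]
        return pd.DataFrame(rows)


def ier_relative_risk(pm25, coeffs: IERCoefficients, disease: str, age_bin: str | None = None):
    """IER relative risk at concentration ``pm25`` (scalar or array)."""
    alpha, gamma, delta = coeffs.triple(disease, age_bin)
    d_pm = np.maximum(np.asarray(pm25, dtype=float) - coeffs.counterfactual, 0.0)
    rr = 1.0 + alpha * (1.0 - np.exp(-gamma * d_pm**delta))
    return rr if rr.ndim else float(rr)


def attributable_deaths(rr, y, population):
    """dM = y * (RR-1)/RR * P element-wise; rejects RR < 1."""
    rr = np.asarray(rr, dtype=float)
    if np.any(rr < 1.0 - 1e-12):
        raise ValueError("relative risk below 1 — upstream computation is broken")
    rr = np.maximum(rr, 1.0)
    af = (rr - 1.0) / rr
    out = np.asarray(y, dtype=float) * af * np.asarray(population, dtype=float)
    return out if out.ndim else float(out)


def age_disaggregate(drivers: ScenarioDrivers, decade: str) -> dict[str, GriddedField]:
    """Grid population per age bin: cell total x national age fraction."""
    fracs = drivers.age_fractions.loc[decade]
    s = float(fracs.sum())
    if abs(s - 1.0) > 1e-9:
        raise ValueError(f"age fractions for {decade} sum to {s!r}, not 1")
    total = drivers.population[decade]
    return {ab: total.copy_with(total.values * float(fracs[ab])) for ab in fracs.index}


def project_gdp(drivers: ScenarioDrivers, decade: str, zone_baseline_gdp):
    """Constant-price zone GDP scaled by the decade's GDP-PPP growth factor.

    The growth factor g = mean(PPP_IIASA, PPP_OECD)/PPP_2010 is applied
    uniformly to every zone.
    """
    return np.asarray(zone_baseline_gdp, dtype=float) * drivers.gdp_growth(decade)


def adjust_baseline_mortality(
    table: BaselineMortalityTable, zone_gdp, disease: str, shift: int = 0
):
    """Baseline mortality rate(s) at the given zone GDP value(s).

    ``shift`` of -1/0/+1 moves the curve coefficients down/centrally/up
    by one standard error (lower/central/higher mortality).
    """
    sub = table.table[table.table["disease"] == disease].sort_values("zone")
    if sub.empty:
        raise KeyError(f"disease {disease!r} not in mortality table")
    a = sub["a"].to_numpy() + shift * sub["se_a"].to_numpy()
    b = sub["b"].to_numpy() - shift * sub["se_b"].to_numpy()
    if np.any(b < 0):
        raise ValueError("negative decline exponent after SE shift; check se_b")
    gdp = np.asarray(zone_gdp, dtype=float)
    y = np.maximum(a, 0.0) * gdp ** (-b)
    return y if y.ndim else float(y)


@dataclass
class MortalityResult:
    """National attributable-mortality estimate for one decade."""

    decade: str
    total: float  # central national deaths / year
    by_disease: dict
    bands: dict  # {"low", "central", "high"} national deaths / year
    grid_total: GriddedField | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        lo, c, hi = self.bands["low"], self.bands["central"], self.bands["high"]
        if not (lo <= c + 1e-9 and c <= hi + 1e-9):
            raise ValueError(f"uncertainty bands out of order: {self.bands}")


def _zone_rate_grids(
    table: BaselineMortalityTable,
    zone_arr: np.ndarray,
    gdp_growth: float,
    shift: int,
) -> dict[str, np.ndarray]:
    """Per-disease gridded baseline mortality at decade GDP."""
    zmax = zone_arr.max()
    safe = np.where(zone_arr >= 0, zone_arr, 0)
    out = {}
    for disease in DISEASES:
        sub = table.table[table.table["disease"] == disease].sort_values("zone")
        gdp = sub["zone_gdp"].to_numpy() * gdp_growth
        y_zone = adjust_baseline_mortality(table, gdp, disease, shift)
        if len(y_zone) <= zmax:
            raise ValueError("zone map references zones missing from the mortality table")
        out[disease] = y_zone[safe]
    return out


def _burden_once(
    pm: np.ndarray,
    mask: np.ndarray,
    pop: np.ndarray,
    age_fracs: pd.Series,
    rates: dict[str, np.ndarray],
    coeffs: IERCoefficients,
) -> tuple[float, dict, np.ndarray]:
    total_grid = np.zeros_like(pm)
    by_disease = {}
    for disease in coeffs.diseases:
        y = rates[disease]
        if disease in AGE_SPECIFIC_DISEASES:
            dm = np.zeros_like(pm)
            for age_bin in AGE_BINS:
                rr = ier_relative_risk(pm, coeffs, disease, age_bin)
                dm += attributable_deaths(rr, y, pop * float(age_fracs[age_bin]))
        else:
            rr = ier_relative_risk(pm, coeffs, disease)
            dm = attributable_deaths(rr, y, pop)
        dm = np.where(mask, dm, 0.0)
        by_disease[disease] = float(dm.sum())
        total_grid += dm
    return float(total_grid.sum()), by_disease, total_grid


def decade_mortality(
    exposure_decade: GriddedField,
    drivers: ScenarioDrivers,
    mortality: BaselineMortalityTable,
    coeffs: IERCoefficients,
    decade: str,
    exposure_sigma: GriddedField | None = None,
    population: GriddedField | None = None,
    age_fractions: pd.Series | None = None,
    gdp_growth: float | None = None,
    uncertainty: str = "joint",
) -> MortalityResult:
    """National attributable deaths for one decade, with uncertainty bands.

    Population, age structure and the GDP growth factor default to the
    decade's driver values but can be overridden (the counterfactual
    sensitivity studies hold individual factors at baseline this way).
    ``uncertainty`` is "joint" (exposure sigma and coefficient SEs shifted
    together, the default) or "quadrature" (the two half-widths combined
    in quadrature around the central value).
    """
    if population is None:
        if decade not in drivers.population:
            raise KeyError(f"decade {decade!r} missing from drivers for {drivers.ssp}")
        population = drivers.population[decade]
    exposure_decade.require_compatible(population)
    if age_fractions is None:
        age_fractions = drivers.age_fractions.loc[decade]
    s = float(age_fractions.sum())
    if abs(s - 1.0) > 1e-9:
        raise ValueError(f"age fractions sum to {s}, not 1")
    if gdp_growth is None:
        gdp_growth = drivers.gdp_growth(decade)

    zone_arr = zone_ids(exposure_decade.grid, exposure_decade.mask, mortality.zones_k)
    mask = exposure_decade.mask
    pop = population.values

    def evaluate(exp_shift: int, coeff_shift: int):
        pm = exposure_decade.values
        if exp_shift and exposure_sigma is not None:
            pm = np.maximum(pm + exp_shift * exposure_sigma.values, 0.0)
        rates = _zone_rate_grids(mortality, zone_arr, gdp_growth, coeff_shift)
        return _burden_once(pm, mask, pop, age_fractions, rates, coeffs)

    central, by_disease, grid_total = evaluate(0, 0)
    if uncertainty == "joint":
        low, _, _ = evaluate(-1, -1)
        high, _, _ = evaluate(+1, +1)
    elif uncertainty == "quadrature":
        lo_e, _, _ = evaluate(-1, 0)
        hi_e, _, _ = evaluate(+1, 0)
        lo_c, _, _ = evaluate(0, -1)
        hi_c, _, _ = evaluate(0, +1)
        low = central - float(np.hypot(central - lo_e, central - lo_c))
        high = central + float(np.hypot(hi_e - central, hi_c - central))
    else:
        raise ValueError(f"unknown uncertainty mode {uncertainty!r}")

    return MortalityResult(
        decade=decade,
        total=central,
        by_disease=by_disease,
        bands={"low": min(low, central), "central": central, "high": max(high, central)},
        grid_total=exposure_decade.copy_with(grid_total, "deaths yr-1"),
    )


def crude_rate(result: MortalityResult, drivers: ScenarioDrivers, decade: str,
               population: GriddedField | None = None) -> float:
    """Attributable deaths per 100,000 exposed (adult) persons."""
    pop = (population or drivers.population[decade]).land_sum()
    if pop <= 0:
        raise ValueError("zero exposed population")
    return 1.0e5 * result.total / pop
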