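"""Combined RCP-SSP scenario matrix and the counterfactual decomposition.

Ten combined scenarios arise from two emission pathways and five
socioeconomic pathways; the (RCP8.5, SSP1) pair is physically
inconsistent (high-emission world, green-growth society) and is refused,
leaving nine feasible cells.  Four sensitivity studies decompose the
projected burden change relative to the baseline-period estimate:

* SA1 — demographic transition only: decade population and age
  structure, everything else at baseline.
* SA2 — epidemiologic transition only: decade GDP-driven baseline
  mortality, everything else at baseline.
* SA3 — climate-change-induced meteorology: burden with emission-only
  (AOD-ratio) exposure minus burden with species-sum exposure, both arms
  sharing the decade's population and mortality.  Positive = deaths
  averted by meteorology.
* SA4 — policy caps: exposure scaled so the national land mean meets a
  WHO interim target (35/25/15 ug m-3 for near/distant/far future);
  reported as burden(capped) - burden(uncapped), i.e. negative when
  deaths are averted.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .exposure import ExposureProjection
from .grid import GriddedField
from .health import (
    BaselineMortalityTable,
    IERCoefficients,
    MortalityResult,
    ScenarioDrivers,
    crude_rate,
    decade_mortality,
)
from .synth import DECADES, SSPS

RCPS = ("rcp45", "rcp85")
INFEASIBLE_PAIRS = frozenset({("rcp85", "ssp1")})

#: decade -> WHO interim-target national-mean cap (ug m-3)
DEFAULT_IT_TARGETS = {"2031-2040": 35.0, "2061-2070": 25.0, "2091-2100": 15.0}
REPRESENTATIVE_DECADES = tuple(DEFAULT_IT_TARGETS)


class InfeasibleScenarioError(ValueError):
    """A scenario pair excluded from the study matrix was requested."""


@dataclass(frozen=True)
class ScenarioSpec:
    rcp: str
    ssp: str

    @property
    def feasible(self) -> bool:
        return (self.rcp, self.ssp) not in INFEASIBLE_PAIRS


def check_pair(rcp: str, ssp: str) -> ScenarioSpec:
    spec = ScenarioSpec(rcp, ssp)
    if not spec.feasible:
        raise InfeasibleScenarioError(
            f"({rcp}, {ssp}) is excluded from the scenario matrix: a high-emission "
            "pathway is inconsistent with the green-growth socioeconomic narrative"
        )
    return spec


def feasible_matrix(rcps=RCPS, ssps=SSPS) -> list[ScenarioSpec]:
    return [ScenarioSpec(r, s) for r in rcps for s in ssps if ScenarioSpec(r, s).feasible]


def baseline_reference(
    baseline_pm25: GriddedField,
    drivers: ScenarioDrivers,
    mortality: BaselineMortalityTable,
    coeffs: IERCoefficients,
) -> MortalityResult:
    """Burden with baseline exposure, first-decade population, unadjusted rates."""
    first = drivers.decades[0]
    return decade_mortality(
        baseline_pm25, drivers, mortality, coeffs, first,
        population=drivers.population[first],
        age_fractions=drivers.age_fractions.loc[first],
        gdp_growth=1.0,
    )


def run_matrix(
    exposures: dict[str, ExposureProjection],
    drivers: dict[str, ScenarioDrivers],
    mortality: BaselineMortalityTable,
    coeffs: IERCoefficients,
    decades: tuple[str, ...] | None = None,
    pairs: list[tuple[str, str]] | None = None,
    uncertainty: str = "joint",
) -> pd.DataFrame:
    """National burden for every requested (rcp, ssp, decade) cell.

    ``pairs`` defaults to the nine feasible combinations; explicitly
    requesting an infeasible pair raises :class:`InfeasibleScenarioError`.
    """
    if pairs is None:
        specs = feasible_matrix(tuple(exposures), tuple(drivers))
    else:
        specs = [check_pair(r, s) for r, s in pairs]
    rows = []
    for spec in specs:
        proj = exposures[spec.rcp]
        drv = drivers[spec.ssp]
        for decade in decades or proj.decades:
            result = decade_mortality(
                proj.decade_mean[decade], drv, mortality, coeffs, decade,
                exposure_sigma=proj.decade_sigma.get(decade),
                uncertainty=uncertainty,
            )
            rows.append({
                "decade": decade, "rcp": spec.rcp, "ssp": spec.ssp,
                "low": result.bands["low"], "central": result.total,
                "high": result.bands["high"],
                "crude_rate": crude_rate(result, drv, decade),
            })
    return pd.DataFrame(rows)


@dataclass
class SensitivityResult:
    """Per-decade burden deltas vs the baseline reference (positive = increase)."""

    study: str
    deltas: pd.DataFrame  # columns: decade, ssp, [rcp], delta (deaths / year)


def sa1_demography(
    baseline_pm25: GriddedField,
    drivers: dict[str, ScenarioDrivers],
    mortality: BaselineMortalityTable,
    coeffs: IERCoefficients,
    decades: tuple[str, ...] = REPRESENTATIVE_DECADES,
) -> SensitivityResult:
    rows = []
    for ssp, drv in drivers.items():
        ref = baseline_reference(baseline_pm25, drv, mortality, coeffs)
        for decade in decades:
            res = decade_mortality(
                baseline_pm25, drv, mortality, coeffs, decade,
                population=drv.population[decade],
                age_fractions=drv.age_fractions.loc[decade],
                gdp_growth=1.0,
            )
            rows.append({"decade": decade, "ssp": ssp, "delta": res.total - ref.total})
    return SensitivityResult("SA1", pd.DataFrame(rows))


def sa2_epidemiology(
    baseline_pm25: GriddedField,
    drivers: dict[str, ScenarioDrivers],
    mortality: BaselineMortalityTable,
    coeffs: IERCoefficients,
    decades: tuple[str, ...] = REPRESENTATIVE_DECADES,
) -> SensitivityResult:
    rows = []
    for ssp, drv in drivers.items():
        first = drv.decades[0]
        ref = baseline_reference(baseline_pm25, drv, mortality, coeffs)
        for decade in decades:
            res = decade_mortality(
                baseline_pm25, drv, mortality, coeffs, decade,
                population=drv.population[first],
                age_fractions=drv.age_fractions.loc[first],
                gdp_growth=drv.gdp_growth(decade),
            )
            rows.append({"decade": decade, "ssp": ssp, "delta": res.total - ref.total})
    return SensitivityResult("SA2", pd.DataFrame(rows))


def sa3_meteorology(
    proj_approach1: dict[str, ExposureProjection],
    proj_approach2: dict[str, ExposureProjection],
    drivers: dict[str, ScenarioDrivers],
    mortality: BaselineMortalityTable,
    coeffs: IERCoefficients,
    decades: tuple[str, ...] = REPRESENTATIVE_DECADES,
) -> SensitivityResult:
    rows = []
    for rcp in proj_approach1:
        p1, p2 = proj_approach1[rcp], proj_approach2[rcp]
        if p1.approach == p2.approach:
            raise ValueError("SA3 needs one projection per estimation approach")
        for spec in feasible_matrix((rcp,), tuple(drivers)):
            drv = drivers[spec.ssp]
            for decade in decades:
                m2 = decade_mortality(p2.decade_mean[decade], drv, mortality, coeffs, decade)
                m1 = decade_mortality(p1.decade_mean[decade], drv, mortality, coeffs, decade)
                rows.append({"decade": decade, "ssp": spec.ssp, "rcp": rcp,
                             "delta": m2.total - m1.total})
    return SensitivityResult("SA3", pd.DataFrame(rows))


def sa4_policy_cap(
    exposure_decade: GriddedField, target: float, mode: str = "uniform"
) -> tuple[GriddedField, float]:
    """Cap the national land-mean exposure at ``target``.

    Returns the (possibly unchanged) capped field and the applied scale
    factor.  ``mode="uniform"`` rescales all land cells multiplicatively;
    ``mode="exceedance"`` instead clips cells above a bisected ceiling so
    only the dirtiest grids are reduced.
    """
    if target <= 0:
        raise ValueError("policy target must be positive")
    nat = exposure_decade.land_mean()
    if nat <= target:
        return exposure_decade, 1.0
    if mode == "uniform":
        factor = target / nat
        capped = exposure_decade.copy_with(exposure_decade.values * factor)
        return capped, factor
    if mode == "exceedance":
        lo, hi = 0.0, float(exposure_decade.values[exposure_decade.mask].max())
        for _ in range(200):
            c = 0.5 * (lo + hi)
            trial = exposure_decade.copy_with(np.minimum(exposure_decade.values, c))
            if trial.land_mean() > target:
                hi = c
            else:
                lo = c
        capped = exposure_decade.copy_with(np.minimum(exposure_decade.values, 0.5 * (lo + hi)))
        return capped, 0.5 * (lo + hi) / nat
    raise ValueError(f"unknown SA4 allocation mode {mode!r}")


def sa4_policy(
    exposures: dict[str, ExposureProjection],
    drivers: dict[str, ScenarioDrivers],
    mortality: BaselineMortalityTable,
    coeffs: IERCoefficients,
    it_targets: dict[str, float] | None = None,
    mode: str = "uniform",
) -> SensitivityResult:
    targets = it_targets or DEFAULT_IT_TARGETS
    rows = []
    for rcp, proj in exposures.items():
        for spec in feasible_matrix((rcp,), tuple(drivers)):
            drv = drivers[spec.ssp]
            for decade, target in targets.items():
                uncapped = proj.decade_mean[decade]
                capped, _ = sa4_policy_cap(uncapped, target, mode=mode)
                m_cap = decade_mortality(capped, drv, mortality, coeffs, decade)
                m_unc = decade_mortality(uncapped, drv, mortality, coeffs, decade)
                rows.append({"decade": decade, "ssp": spec.ssp, "rcp": rcp,
                             "delta": m_cap.total - m_unc.total})
    return SensitivityResult("SA4", pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def pct_increase_bounds(central: pd.DataFrame) -> pd.DataFrame:
    """Cross-SSP min/max percentage increase of the high-emission column.

    ``central`` has columns decade, ssp, rcp45, rcp85 (national burden).
    Returns one row per decade with the min and max (to one decimal) of
    100 * (rcp85 - rcp45)/rcp45 across the SSP columns present.
    """
    pct = 100.0 * (central["rcp85"] - central["rcp45"]) / central["rcp45"]
    frame = central.assign(pct=pct)
    out = frame.groupby("decade")["pct"].agg(["min", "max"]).reset_index()
    out["min"] = out["min"].round(1)
    out["max"] = out["max"].round(1)
    return out


def load_reference_burden_table() -> pd.DataFrame:
    """Published decadal national burden (millions/yr) per RCP-SSP cell.

    Shipped as a consistency fixture for cross-scenario ratio checks; the
    pipeline never uses it as an input.
    """
    with resources.files("pm25burden.data").joinpath("reference_burden_table.csv").open() as fh:
        return pd.read_csv(fh)


def matrix_to_central_table(matrix: pd.DataFrame) -> pd.DataFrame:
    wide = matrix.pivot_table(index=["decade", "ssp"], columns="rcp", values="central").reset_index()
    wide.columns.name = None
    return wide


def report_tables(
    matrix: pd.DataFrame,
    sensitivities: list[SensitivityResult],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the burden matrix, SA deltas and RCP-increase tables as CSVs.

    Burden is reported in millions per year (2 decimals) with low/high
    bands; SA deltas in thousands per year (1 decimal).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    burden = matrix.copy()
    for col in ("low", "central", "high"):
        burden[col] = (burden[col] / 1e6).round(2)
    burden["crude_rate"] = burden["crude_rate"].round(1)
    p = out / "burden_matrix.csv"
    burden.to_csv(p, index=False)
    written["burden_matrix"] = p

    for sres in sensitivities:
        d = sres.deltas.copy()
        d["delta_thousands"] = (d["delta"] / 1e3).round(1)
        d = d.drop(columns=["delta"])
        p = out / f"sensitivity_{sres.study.lower()}.csv"
        d.to_csv(p, index=False)
        written[sres.study] = p

    central = matrix_to_central_table(matrix)
    if {"rcp45", "rcp85"} <= set(central.columns):
        # drop SSP rows that lack either column (infeasible cell)
        both = central.dropna(subset=["rcp45", "rcp85"])
        p = out / "rcp_increase_pct.csv"
        pct_increase_bounds(both).to_csv(p, index=False)
        written["rcp_increase"] = p
    return written
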