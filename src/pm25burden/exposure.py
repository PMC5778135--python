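"""Per-model PM2.5 estimation and multi-model exposure projection.

Two estimation approaches are supported for each ensemble member:

* **species_sum** — PM2.5 built from the member's reported aerosol
  species, ``BC + OA + SO4 + NH4 + 0.25*SS + 0.1*dust`` with ammonium
  assumed present only as ammonium sulphate (NH4 = 36*SO4/96) and
  POA/SOA reporting gaps filled from a reference member's POA:SOA ratio;
* **aod_ratio** — the member's AOD converted to surface PM2.5 with the
  baseline-period conversion factor eta = PM2.5/AOD, held fixed for all
  future windows so the result carries the emission signal only.

Member projections apply the member's pentad-vs-baseline relative change
back onto the satellite-derived baseline exposure, which sidesteps the
models' large absolute biases.  Ensemble mean +/- 1 sigma summarises the
13-member spread; two consecutive pentads average to a decadal surface,
and the approach2 - approach1 difference isolates the meteorological
contribution of climate change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grid import GriddedField, GridMismatchError
from .synth import DECADE_PENTADS, DECADES, ModelPentadRecord

logger = logging.getLogger(__name__)

APPROACHES = ("species_sum", "aod_ratio")

NH4_PER_SO4 = 36.0 / 96.0  # ammonium sulphate stoichiometry
SS_PM25_FRACTION = 0.25
DUST_PM25_FRACTION = 0.1

_REQUIRED_SPECIES = ("BC", "SO4", "SS", "dust")


class MissingSpeciesError(ValueError):
    """A record lacks a species the estimator needs."""


def pm25_from_species(record: ModelPentadRecord, reference: ModelPentadRecord) -> GriddedField:
    """Species-sum PM2.5 for one member record (estimation approach 1).

    ``reference`` must report both POA and SOA; its cell-wise POA:SOA
    ratio imputes whichever organic component the record lacks.  Cells
    where the reference denominator is zero get an imputed value of 0
    (counted and logged).
    """
    sp = record.species
    for name in _REQUIRED_SPECIES:
        if name not in sp:
            raise MissingSpeciesError(f"record {record.model_id}/{record.pentad} lacks {name}")
    base = sp["BC"]

    if "OA" in sp:
        oa = sp["OA"].values
    else:
        if "POA" not in reference.species or "SOA" not in reference.species:
            raise MissingSpeciesError(
                f"reference member {reference.model_id} must report both POA and SOA"
            )
        ref_poa = reference.species["POA"].values
        ref_soa = reference.species["SOA"].values
        if "POA" in sp and "SOA" in sp:
            oa = sp["POA"].values + sp["SOA"].values
        elif "POA" in sp:
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(ref_poa > 0, ref_soa / np.where(ref_poa > 0, ref_poa, 1.0), 0.0)
            n_zero = int(((ref_poa <= 0) & base.mask).sum())
            if n_zero:
                logger.warning("POA->SOA imputation: %d land cells with zero reference POA set to 0", n_zero)
            oa = sp["POA"].values * (1.0 + ratio)
        elif "SOA" in sp:
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(ref_soa > 0, ref_poa / np.where(ref_soa > 0, ref_soa, 1.0), 0.0)
            n_zero = int(((ref_soa <= 0) & base.mask).sum())
            if n_zero:
                logger.warning("SOA->POA imputation: %d land cells with zero reference SOA set to 0", n_zero)
            oa = sp["SOA"].values * (1.0 + ratio)
        else:
            raise MissingSpeciesError(
                f"record {record.model_id}/{record.pentad} reports neither OA nor POA/SOA"
            )

    pm = (
        sp["BC"].values
        + oa
        + sp["SO4"].values * (1.0 + NH4_PER_SO4)
        + SS_PM25_FRACTION * sp["SS"].values
        + DUST_PM25_FRACTION * sp["dust"].values
    )
    return base.copy_with(pm, "ug m-3")


@dataclass
class ConversionFactor:
    """Fixed baseline-period PM2.5/AOD ratio on the analysis grid."""

    eta: GriddedField


def compute_eta(baseline_pm25: GriddedField, baseline_aod: GriddedField) -> ConversionFactor:
    """eta = PM2.5/AOD cell-wise; rejects non-positive AOD on land."""
    baseline_pm25.require_compatible(baseline_aod)
    bad = (baseline_aod.values <= 0) & baseline_aod.mask
    if bad.any():
        idx = np.argwhere(bad)[:10]
        raise ValueError(f"non-positive baseline AOD on {int(bad.sum())} land cells, e.g. {idx.tolist()}")
    with np.errstate(divide="ignore", invalid="ignore"):
        eta = np.where(baseline_aod.values > 0, baseline_pm25.values / np.where(
            baseline_aod.values > 0, baseline_aod.values, 1.0), 0.0)
    return ConversionFactor(baseline_pm25.copy_with(eta, "ug m-3 per AOD"))


def pm25_from_aod(aod: GriddedField, eta: ConversionFactor) -> GriddedField:
    """AOD-ratio PM2.5 (estimation approach 2): cell-wise AOD * eta."""
    aod.require_compatible(eta.eta)
    return aod.copy_with(aod.values * eta.eta.values, "ug m-3")


def project_pentad(
    model_pentad_pm25: GriddedField,
    model_baseline_pm25: GriddedField,
    satellite_baseline: GriddedField,
) -> GriddedField:
    """Scale the satellite baseline by the member's relative change.

    ``proj = sat + sat * (model_pentad - model_baseline)/model_baseline``.
    Tiny floating-point negatives are floored at zero (count logged).
    """
    model_pentad_pm25.require_compatible(model_baseline_pm25)
    model_pentad_pm25.require_compatible(satellite_baseline)
    bl = model_baseline_pm25.values
    zero_bl = (bl <= 0) & satellite_baseline.mask
    if zero_bl.any():
        raise ValueError(
            f"model baseline PM2.5 non-positive on {int(zero_bl.sum())} land cells; relative change undefined"
        )
    rel = (model_pentad_pm25.values - bl) / np.where(bl > 0, bl, 1.0)
    proj = satellite_baseline.values * (1.0 + rel)
    neg = (proj < 0) & satellite_baseline.mask
    if neg.any():
        logger.warning("floored %d negative projected cells at 0", int(neg.sum()))
        proj = np.where(neg, 0.0, proj)
    return satellite_baseline.copy_with(proj, "ug m-3")


def ensemble_summarize(member_fields: list[GriddedField]) -> tuple[GriddedField, GriddedField]:
    """Cell-wise arithmetic mean and sample (n-1) standard deviation."""
    if len(member_fields) < 2:
        raise ValueError(f"need >= 2 members to summarise, got {len(member_fields)}")
    first = member_fields[0]
    for f in member_fields[1:]:
        first.require_compatible(f)
    stack = np.stack([f.values for f in member_fields])
    return (
        first.copy_with(stack.mean(axis=0)),
        first.copy_with(stack.std(axis=0, ddof=1)),
    )


def decade_average(pentad_a: GriddedField, pentad_b: GriddedField,
                   labels: tuple[str, str] | None = None) -> GriddedField:
    """Mean of two consecutive pentads; validates consecutiveness if labelled."""
    pentad_a.require_compatible(pentad_b)
    if labels is not None:
        a, b = labels
        try:
            end_a = int(a.split("-")[1])
            start_b = int(b.split("-")[0])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"unparseable pentad labels {labels}") from exc
        if start_b != end_a + 1:
            raise ValueError(f"pentads {a!r} and {b!r} are not consecutive")
    return pentad_a.copy_with(0.5 * (pentad_a.values + pentad_b.values))


@dataclass
class ExposureProjection:
    """Projected exposure surfaces for one scenario and approach."""

    scenario: str
    approach: str
    pentads: tuple[str, ...]
    member_pentad: dict = field(repr=False)  # pentad -> list[GriddedField], model order
    mean: dict = field(default_factory=dict, repr=False)      # pentad -> GriddedField
    sigma: dict = field(default_factory=dict, repr=False)     # pentad -> GriddedField
    decade_member: dict = field(default_factory=dict, repr=False)  # decade -> list[GriddedField]
    decade_mean: dict = field(default_factory=dict, repr=False)
    decade_sigma: dict = field(default_factory=dict, repr=False)

    def summarize(self) -> "ExposureProjection":
        for pentad, members in self.member_pentad.items():
            self.mean[pentad], self.sigma[pentad] = ensemble_summarize(members)
        for decade in DECADES:
            pa, pb = DECADE_PENTADS[decade]
            if pa not in self.member_pentad or pb not in self.member_pentad:
                continue
            members = [
                decade_average(fa, fb, labels=(pa, pb))
                for fa, fb in zip(self.member_pentad[pa], self.member_pentad[pb])
            ]
            self.decade_member[decade] = members
            self.decade_mean[decade], self.decade_sigma[decade] = ensemble_summarize(members)
        return self

    @property
    def decades(self) -> tuple[str, ...]:
        return tuple(d for d in DECADES if d in self.decade_mean)


def project_scenario(
    records: list[ModelPentadRecord],
    satellite_baseline: GriddedField,
    approach: str,
    eta: ConversionFactor | None = None,
    reference_model: str = "model01",
    ensemble_mean_relative_change: bool = False,
) -> ExposureProjection:
    """Run the full member-by-member projection for one scenario.

    By default the relative change is computed per model and the ensemble
    is summarised afterwards (sigma needs per-model surfaces); setting
    ``ensemble_mean_relative_change`` instead averages member PM2.5
    before forming a single relative change, the variant in which the
    central estimate uses the mean relative change across the ensemble.
    """
    if approach not in APPROACHES:
        raise ValueError(f"unknown approach {approach!r}; expected one of {APPROACHES}")
    if approach == "aod_ratio" and eta is None:
        raise ValueError("aod_ratio approach requires a ConversionFactor")

    scenario = records[0].scenario
    by_model: dict[str, dict[str, ModelPentadRecord]] = {}
    for rec in records:
        if rec.scenario != scenario:
            raise ValueError("records mix scenarios")
        by_model.setdefault(rec.model_id, {})[rec.pentad] = rec

    baseline_label = next(
        p for recs in by_model.values() for p in recs if p.startswith("200")
    )
    pentads = tuple(
        sorted({p for recs in by_model.values() for p in recs if p != baseline_label})
    )

    def member_pm(rec: ModelPentadRecord) -> GriddedField:
        if approach == "species_sum":
            ref = by_model[reference_model][rec.pentad]
            return pm25_from_species(rec, ref)
        return pm25_from_aod(rec.aod, eta)

    member_pentad: dict[str, list[GriddedField]] = {p: [] for p in pentads}
    model_ids = sorted(by_model)
    if ensemble_mean_relative_change:
        bl_mean, _ = ensemble_summarize([member_pm(by_model[m][baseline_label]) for m in model_ids])
        for p in pentads:
            p_mean, _ = ensemble_summarize([member_pm(by_model[m][p]) for m in model_ids])
            proj = project_pentad(p_mean, bl_mean, satellite_baseline)
            member_pentad[p] = [proj, proj]  # duplicated so summary stats still work
    else:
        for m in model_ids:
            recs = by_model[m]
            if baseline_label not in recs:
                raise ValueError(f"member {m} lacks a baseline-window record")
            bl_pm = member_pm(recs[baseline_label])
            for p in pentads:
                member_pentad[p].append(project_pentad(member_pm(recs[p]), bl_pm, satellite_baseline))

    return ExposureProjection(
        scenario=scenario, approach=approach, pentads=pentads, member_pentad=member_pentad
    ).summarize()


def meteorology_delta(
    proj_approach2: ExposureProjection, proj_approach1: ExposureProjection
) -> dict[str, GriddedField]:
    """Per-decade (approach2 - approach1) surfaces.

    Positive values mean climate-change-induced meteorology suppresses
    exposure (the emission-only approach-2 surface sits above what the
    species path, which feels the meteorology, produced).
    """
    if proj_approach2.scenario != proj_approach1.scenario:
        raise GridMismatchError(
            f"scenario mismatch: {proj_approach2.scenario} vs {proj_approach1.scenario}"
        )
    out = {}
    for decade in proj_approach2.decades:
        if decade not in proj_approach1.decade_mean:
            continue
        a2 = proj_approach2.decade_mean[decade]
        a1 = proj_approach1.decade_mean[decade]
        a2.require_compatible(a1)
        out[decade] = a2.copy_with(a2.values - a1.values)
    return out
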