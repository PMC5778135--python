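# pm25burden

Projection of ambient fine-particulate (PM₂.₅) exposure through 2100 and
the premature-mortality burden attributable to it, across combined
climate (RCP) and socioeconomic (SSP) scenario analogues, with a
counterfactual decomposition of the burden into its drivers.

The package is aimed at air-quality and environmental-health modellers
who want a fully testable, self-contained implementation of the
multi-model relative-change exposure projection and the integrated
exposure–response (IER) health-impact chain. All inputs are produced by
a seeded synthetic generator that emulates the statistical structure of
the real data sources (a satellite-derived baseline exposure raster, a
13-member climate-model ensemble, SSP-style demographic and economic
drivers), so every stage runs and is verifiable without any download.

## The model

**Exposure.** Each ensemble member's PM₂.₅ is estimated two ways:

- *approach 1 (species sum)*:
  PM₂.₅ = BC + OA + SO₄ + NH₄ + 0.25·SS + 0.1·dust, with
  NH₄ = 36·SO₄/96 (ammonium assumed present only as ammonium sulphate)
  and missing POA/SOA components imputed from a reference member's
  POA:SOA ratio;
- *approach 2 (AOD ratio)*: the member's aerosol optical depth times a
  fixed baseline-period conversion factor η = PM₂.₅/AOD per grid cell,
  so the result carries the emission signal but not the meteorology.

Because climate models carry large absolute biases over the study
domain, each member's *relative* change is applied back onto the
satellite-derived baseline exposure:

    PM(pentad x) = PM_sat(baseline) · [1 + (PM_mod(x) − PM_mod(bl)) / PM_mod(bl)]

The ensemble is summarised cell-wise as mean ± 1σ; two consecutive
pentads average to a decadal surface; the approach 2 − approach 1
difference isolates the meteorological contribution of climate change.

**Health impact.** Relative risk follows the IER function

    RR = 1 + α·[1 − exp(−γ·ΔC^δ)],   ΔC = max(C − C₀, 0),  C₀ = 5.8 µg m⁻³

for COPD, ischaemic heart disease, stroke and lung cancer (age-specific
coefficients for IHD and stroke), and attributable deaths per cell are

    ΔM = y · (RR − 1)/RR · P

with the baseline mortality rate y inherited from the cell's state and
declining with projected GDP as y = a·GDP^(−b) (lung cancer is held
GDP-invariant). Population is allocated from national SSP totals by a
fixed settlement field and split into 5-year adult age bins by national
fractions. Uncertainty bands evaluate the whole chain at mean ∓ 1σ
exposure jointly with the mortality coefficients shifted by ∓ 1 SE.

**Attribution.** Nine feasible RCP×SSP cells (the high-emission ×
green-growth pair is refused) are evaluated per decade, plus four
counterfactuals: SA1 (demography only), SA2 (epidemiologic transition
only), SA3 (meteorology, approach 2 − approach 1) and SA4 (exposure
capped so the national mean meets WHO interim targets 35/25/15 µg m⁻³
in the near/distant/far future).

## Worked example

The numbered drivers under `analysis/` run the study end to end at the
default size (0.5° grid over 6.5–37.5°N, 67.5–97.5°E; 13 members; 18
pentads; the whole sequence takes well under a minute on one CPU):

```sh
python analysis/01_simulate.py        # generate + persist the input bundle
python analysis/02_project_exposure.py
python analysis/03_burden_matrix.py
python analysis/04_sensitivity.py
python analysis/05_report.py
```

`02_project_exposure.py` prints, for the default seed:

```
baseline national mean: 34.50 ug m-3
rcp45: peak 40.5 ug m-3 in 2026-2030, drops below baseline in 2051-2055
  meteorology modifies exposure by -7.3% in 2011-2020 (positive = enhancement)
  meteorology modifies exposure by -16.7% in 2091-2100 (positive = enhancement)
rcp85: peak 49.3 ug m-3 in 2036-2040, drops below baseline in 2091-2095
```

i.e. the stabilisation-scenario exposure peaks in the late 2020s and the
meteorological suppression planted by the generator (growing from 7% to
17% over the century) is recovered by the approach-2 − approach-1
difference. `03_burden_matrix.py` then reports

```
2011-2020: burden ranges 0.44M (ssp5-rcp45) to 0.46M (ssp3-rcp85) deaths/yr
2091-2100: burden ranges 0.07M (ssp5-rcp45) to 0.47M (ssp3-rcp85) deaths/yr
ssp3-rcp85 is the maximal cell in every decade: True
```

— the burden declines everywhere except under the combination of the
high-emission exposure with the only monotonically growing population
pathway, which stays at its baseline level. The formatted tables land
under `results/tables/` (burden in millions/yr, sensitivity deltas in
thousands/yr, and the cross-SSP percentage excess of RCP8.5 over
RCP4.5 per decade).

The same pipeline is scriptable through the `pm25burden` console
command (`simulate`, `project-exposure`, `project-mortality`,
`run-matrix`, `sensitivity`, `report`).

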