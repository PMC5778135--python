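# Methods

This note documents the models, the synthetic study conditions, the
numerical choices and the known limitations of `pm25burden`.

## Exposure projection

### Estimation approaches

Each ensemble member's surface PM₂.₅ is estimated in two independent
ways.

**Species sum.** PM₂.₅ = BC + OA + SO₄ + NH₄ + 0.25·SS + 0.1·dust.
Ammonium is not reported by the members and is reconstructed
stoichiometrically as ammonium sulphate, NH₄ = (36/96)·SO₄. The sea-salt
and dust factors are the fixed fine-fraction shares, applied uniformly
over the domain. Organic aerosol handling mirrors heterogeneous
reporting: members reporting total OA use it directly; a member
reporting only POA (or only SOA) has the missing component imputed
cell-wise from the reference member's SOA:POA ratio. Cells where the
reference denominator is zero get an imputed component of zero and the
count is logged rather than raised, since such cells are legitimate
(zero-organic ocean cells) and the mask excludes them from national
statistics.

**AOD ratio.** The member's AOD times the conversion factor
η = PM₂.₅/AOD, computed once from the baseline pair and held fixed for
all future windows. Because η encodes baseline meteorology
(vertical profile, humidity growth), keeping it frozen means the
AOD path responds to emissions only; the species path responds to both.
Their difference is therefore the meteorological contribution of
climate change, which is exactly how the pipeline isolates it (SA3).

### Relative-change scaling

Climate models misestimate absolute aerosol levels over the domain by
large factors, so member fields are never used in absolute terms.
For member m and pentad x:

    PM_proj(m, x) = PM_sat · [1 + (PM_mod(m,x) − PM_mod(m,bl)) / PM_mod(m,bl)]

The relative change is computed **per member** and the ensemble is
summarised afterwards (arithmetic mean, sample SD with n−1); the
variant that averages member PM₂.₅ first and forms a single relative
change is available via `ensemble_mean_relative_change=True`. The
per-member default was chosen because the spread across members is
needed for the uncertainty bands, and with the pooled variant there is
no member-resolved σ. A member baseline of zero on a land cell is an
error (relative change undefined); tiny negative projected values from
floating-point noise are floored at zero with a logged count.

### Calendars and aggregation

Pentads run 2011–2015 … 2096–2100 (18 windows); decade d averages
pentads 2d−1 and 2d cell-wise. National means are cos(latitude)-weighted
over land cells (a physical area mean; plain cell averages would
overweight the northern rows by ~10% over this domain). Downscaling of
coarse member grids is bilinear interpolation of cell-centre values
(deterministic, exact on linear fields), with nearest-neighbour behind
a switch; intensive quantities only, no area re-weighting.

## Health impact

Relative risk uses the integrated exposure–response form
RR = 1 + α(1 − exp(−γ·ΔC^δ)) with ΔC floored at zero below the
counterfactual concentration (5.8 µg m⁻³), so RR ∈ [1, 1+α] and is
monotone in concentration for all positive coefficient triples.
The coefficient triples are supplied as a CSV (`disease, age_bin,
alpha, gamma, delta`); the shipped set under
`src/pm25burden/data/ier_coefficients_synthetic.csv` is **illustrative
and non-authoritative** — it has the right structure (one triple for
COPD and LC, one per 5-year adult age bin for IHD and stroke, with risk
declining with age) but the values are not taken from any
epidemiological fit, and no test asserts a specific epidemiological
value against them.

Attributable deaths per cell are ΔM = y·(RR−1)/RR·P. For COPD and LC,
P is the full adult (>25 y) cell population; for IHD and stroke the
cell population is split into age bins by national fractions and
per-bin RR contributions are summed. Populations are the first year of
each decade (the minimum population exposed to that decade's surface).

Baseline mortality y is per state ("zone") and disease, declining with
GDP as y = a·GDP^(−b); a is anchored so that y equals the tabulated
baseline rate at the zone's baseline GDP. Lung cancer has b = 0
(GDP-invariant). Decade GDP applies the national growth factor
g = mean(PPP_IIASA, PPP_OECD)/PPP_2010 uniformly to every zone. The
printed form of the GDP update in the source material mixes a ratio and
a subtraction inconsistently; the implemented form follows the prose
(GDP scales with the rate of change of the averaged GDP-PPP relative to
the 2010 reference), which also reproduces the stated behaviour at
g = 1. GDP is expressed in units where all values exceed 1, so shifting
b by its standard error moves y monotonically and the bands below stay
ordered.

**Uncertainty bands.** low/high evaluate the full chain at mean ∓ 1σ
exposure (floored at 0) *jointly* with (a, b) shifted by ∓ 1 SE — the
joint convention follows the stated construction of the published
bands; combining the two sources in quadrature is available via
`uncertainty="quadrature"`. Monotonicity of the chain in both inputs
guarantees low ≤ central ≤ high.

## Scenario matrix and counterfactuals

Two emission pathways × five socioeconomic pathways give ten cells;
(rcp85, ssp1) is inconsistent by narrative and requesting it raises an
error rather than being skipped silently, leaving nine cells. The
central matrix uses the species-sum (approach 1) exposure.

All SA deltas are taken against the same reference: burden computed
with baseline exposure, first-decade population and age structure, and
unadjusted (g = 1) mortality rates.

- **SA1** substitutes the decade's population grid *and* age fractions
  (demography includes ageing), everything else at baseline.
- **SA2** substitutes the decade's GDP-driven rates only.
- **SA3** differences the two estimation approaches with the decade's
  population and rates in both arms; positive values mean meteorology
  averts deaths.
- **SA4** caps the decade surface so the national mean meets the WHO
  interim target mapped to that decade (near 35, distant 25, far
  15 µg m⁻³). The default allocation scales all land cells by one
  factor (parameter-free, reproducible); a "clip the dirtiest cells
  first" alternative, implemented by bisecting a ceiling value, is
  available via `mode="exceedance"`. Reported as capped − uncapped
  (negative = averted).

Under uniform scalings the decomposition is exact: scaling population
by c and rates by d changes the burden by
(c−1)·M + (d−1)·M + (c−1)(d−1)·M, which the tests assert.

## Synthetic study conditions

The generator is a pure function of (seed, config); identical inputs
give bit-identical bundles (verified by manifest checksums).

- **Domain**: 0.5° grid over 6.5–37.5°N, 67.5–97.5°E with an elliptical
  procedural land mask (seed-independent, so all rasters share it);
  states are a 4×4 rectangular partition of the box.
- **Baseline field**: smooth positive background (exponentiated,
  spatially smoothed Gaussian noise) scaled so the area-weighted land
  mean is exactly 34.5 µg m⁻³, plus a Gaussian hotspot (amplitude
  30 µg m⁻³, radius 4°, centred at 26.5°N 82°E — an Indo-Gangetic-basin
  analogue). η is a smooth field in 35–65 µg m⁻³ per unit AOD and
  AOD = PM₂.₅/η by construction.
- **Ensemble**: 13 members. Member m carries a fixed multiplicative
  lognormal bias field (log-SD 0.3, spatially smoothed) shared by its
  baseline and future records, plus per-(member, pentad) lognormal
  noise (log-SD 0.08). The bias cancels exactly in the relative change,
  so with noise off the planted national trend is recovered to machine
  precision while noise on yields a member spread at every cell. The
  smoothing length scale of the noise (3 cells) is a free knob: the
  spatial covariance of inter-model disagreement is not a calibrated
  quantity.
- **Planted scenario signals**: per-pentad emission trends for the two
  scenario analogues are chosen so the stabilisation pathway peaks in
  the 2020s and falls below baseline after 2050 while the high-emission
  pathway peaks around 2040 and falls below baseline only after 2090;
  the meteorology modifier for the stabilisation analogue grows from
  −7% to −17% across the century, and for the high-emission analogue is
  weakly negative early, positive mid-century and weakly negative in
  the last decade. These shapes are the study conditions the planted
  signal tests recover; they are not fit to any archive.
- **Drivers**: national adult totals per decade per SSP analogue, with
  exactly one monotone pathway (the ssp3 analogue, 0.68 → 1.45 bn) and
  the others peaking strictly before 2091. Spatial allocation follows a
  fixed settlement field, so cell shares are decade- and SSP-invariant.
  Age fractions are a geometric profile whose ratio drifts from 0.78 to
  0.92 across decades, shifting mass into older bins. GDP-PPP growth
  multipliers are strictly increasing and diverge across pathways from
  the first decade (fastest for the ssp5 analogue, slowest for ssp3);
  the IIASA-like and OECD-like trajectories straddle the common curve
  at ±5%.
- **Mortality**: national baseline rates per adult per year
  (COPD 1.2e-3, IHD 2.2e-3, stroke 1.1e-3, LC 1.5e-4) with decline
  exponents 0.45/0.35/0.40/0 and relative coefficient SEs of ~10%;
  zone GDPs spread ±30% around the national baseline.

### What the generator does *not* emulate

Real satellite retrieval error and its bias correction; model-specific
physics and resolutions (all members share the analysis grid, so the
downscaling operator is exercised by its own tests, not by the
pipeline); realistic administrative boundaries; migration and
urbanisation (settlement shares are frozen); correlation between
exposure and settlement trends. Passing tests therefore demonstrate the
correctness and internal consistency of the method chain under known
conditions — not the magnitude of any real-world burden. Absolute
burden numbers from the synthetic study are not comparable to published
estimates for India; the only published values used are the shipped
decadal burden table, used solely for cross-scenario ratio consistency
checks.

## Numerical choices and degenerate inputs

- Sample SD uses n−1; ensembles of fewer than two members are refused.
- Age fractions must sum to 1 within 1e-9; zone maps referencing zones
  missing from the mortality table are an error.
- RR below 1 entering the death computation is an error (upstream bug),
  not a clamp.
- The SA4 bisection runs 200 halvings (ample for 1e-6 relative accuracy
  on the capped mean).
- NetCDF is written in classic format via the scipy backend with
  float64 payloads, giving bit-identical round trips; descending
  latitude on read is re-oriented north-up.
- Problem sizes: tests run on a 20×20 (or smaller) sub-grid with 5
  members; the analysis drivers and the acceptance script run the full
  62×60 domain with 13 members, which completes in seconds. These sizes
  were chosen so the synthetic study remains comfortably interactive.

## Known limitations

- The IER coefficient set is structural, not epidemiological; users
  with access to fitted lookup tables should supply them as CSV.
- The GDP→mortality family is a two-parameter power law; the real
  relation was only characterised as "non-linear decline", so the
  family is pluggable at the table level (any (a, b) per zone/disease;
  an exponential-decay variant can be expressed by resampling the
  table per decade).
- Meteorology enters the generator as a national scalar per pentad;
  real meteorological modulation is spatially structured.
- Ozone and secondary-formation health effects are out of scope, as is
  any emission-sector attribution.
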