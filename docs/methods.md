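# Methods

## The budget model

`nbudget` implements a soil-surface nitrogen balance for agricultural land,
resolved by district and calendar year:

```
NS(i, y) = N_DEP + N_FERT + N_BNF + N_MAN − N_CROP     [kg N ha⁻¹ yr⁻¹]
```

All components are gross fluxes (≥ 0); only the surplus may be negative
(harvest removing more N than was supplied, mined from soil stocks). Units
are fixed internally — masses in kg N, areas in ha, rates in
kg N ha⁻¹ yr⁻¹ — and every file reader converts at the boundary.

Two **area bases** are supported and never mixed: rates per *net cropped
area* (NCA, land sown at least once) and per *gross cropped area* (GCA ≥
NCA, counting multiple croppings). Net-basis rates are the headline
field-intensity numbers; gross-basis rates are the convention for
comparisons with national budget datasets, which mostly normalize by total
cropping area. Every `ComponentSeries` records its basis and
`member_surplus` refuses to combine series on different denominators.

### Components

**Fertilizer.** `N_FERT = total N applied / area(basis)`. District panels
report one total synthetic-N figure, so no crop-wise allocation is
attempted.

**Deposition.** A gridded monthly total-N deposition field (typically
1.9° × 2.5°, ending 2014) is summed to annual values (an error is raised
for partial years), sampled at district centroids by nearest-neighbour
using great-circle (haversine) distance — ties break to the lowest latitude
index, then longitude index — and scaled to cropland:
`load = flux × district_area × cropland_fraction`, stored as `load / area(basis)`.
The cropland-scaling term is interpreted as scaling a *load*, not a rate;
when cropland area equals the NCA the net-basis rate reduces to the raw
flux. Fields shipped as SI fluxes (kg m⁻² s⁻¹) are converted at the read
boundary via seconds-in-calendar-month × 10⁴ m² ha⁻¹. Years past the
field's end are filled by last-value carry-forward; the choice is recorded
in the run's provenance.

**Biological fixation**, two methods:

* *yield-based*: per fixing crop, `%Ndfa × Y × NHI × BGN`, with `Y` the
  crop's N yield (production × N content / harvested area, kg N ha⁻¹).
  `%Ndfa` is the share of crop N derived from fixation, `NHI` the nitrogen
  harvest index, `BGN` a below-ground multiplier for roots, nodules and
  rhizodeposition. Contributions are area-weighted (`CA_c / area(basis)`)
  into the district rate, making the method dimensionally parallel to the
  area-based one. `Y` uses the same N-content source as the paired removal
  estimate, so yield-based BNF varies (slightly) across the removal axis.
  The `nhi_mode` switch (`multiply`, default | `divide`) controls whether
  NHI multiplies the N yield or divides it (the form that recovers total
  plant N from harvested N); the choice is stamped into the method tag.
* *area-based*: `Σ_c CA_c × rate_c / area(basis)` with literature
  per-crop fixation rates.

Free-living / non-symbiotic fixation is not modelled.

**Manure**, three estimates:

1. *census × global fractions*: per-head excretion
   `N_ex = n_rate × (TAM/1000) × 365` (excretion rate in
   kg N (1000 kg animal mass)⁻¹ day⁻¹, TAM the typical animal mass),
   times livestock density (head per basis-area ha), times the applied
   share `F_M = Σ_ProSys share × F_MT·(1−F_MO)·(1−F_Loss)` averaged over
   production systems (irrigated/rainfed; a single national split,
   default 0.4/0.6, since district shares are rarely known), summed over
   all categories.
2. *census × India fractions*: same excretion, restricted to the ruminant
   categories (cattle, buffalo, goats, sheep), times
   `1 − (AM_CN + AM_CL + AM_FL)` — the shares lost in collection, used as
   construction material, and burnt as fuel.
3. *gridded product*: an external manure-application grid sampled at
   centroids with the same nearest-neighbour rule and carried forward at a
   constant rate past its final year (the convention for 2015–2017 when
   the product ends in 2014). Gridded rates are interpreted as per-NCA
   rates; gross-basis conversion goes through the load (`rate × NCA / GCA`).

Quinquennial censuses are annualized by **linear interpolation** between
census years with flat extrapolation outside the census range — exact at
censuses, no overshoot. Only cropland application is accounted; manure
left on pasture is out of scope.

**Crop removal.** `N_CROP = Σ_c production_c × N_content(c, source) / area(basis)`,
with a uniform per-crop N content from one of two sources (`FAO`,
`BOUWMAN`). Regional and temporal variation in N content is deliberately
ignored (data are not available at this scale); the two-source spread is
the uncertainty handle.

### The ensemble

The Cartesian product of 3 manure × 2 BNF × 2 removal choices gives 12
equal-weight members; fertilizer and deposition are computed once and
shared. Member IDs are canonical strings `man-{g|i|z}_bnf-{y|a}_upt-{f|b}`.
Summaries per district-year: mean, Q1, Q3, IQR = Q3 − Q1 and the sample
standard deviation (n − 1). Quartiles use linear interpolation of order
statistics (numpy's default); no convention is canonical here, so the
choice is fixed and documented. IQR is the headline district uncertainty
measure; the ±1 sd band is used for national coverage checks.

### Aggregation

Regions are abstract district → region assignments (no polygons; mappings
are precomputed inputs). A region's total load is
`Σ_districts rate × weight_area` with year-specific cropped area of the
series' basis as weight, and the region rate is total load / total weight
— so loads are conserved exactly and the national rate is the area-weighted
mean (an equal-weight mode exists for sensitivity). Ensembles are
aggregated **member-wise before summarizing**, so regional IQRs measure
methodological spread, not inter-district variability.

### Validation tools

National per-ha or total (Tg N = kg × 10⁻⁹) series per member are compared
with reference country-level budgets via the coefficient of determination
of an OLS fit with intercept (numerically the squared Pearson correlation,
hence affine-invariant), reported as mean ± sd over the 12 members, plus a
per-year flag for whether the reference falls inside the ensemble's
mean ± 1 sd band. Reference series are plain CSVs aligned by calendar
year; at least 3 overlapping years are required and zero-variance series
leave R² undefined (flagged, NaN).

## Synthetic data

`nbudget.synth.generate_bundle` emulates the *shape* of a half-century
Indian district panel — not its magnitudes beyond order of magnitude:

* default 25 districts in 5 states, 1966–2017;
* fertilizer rates follow a logistic trajectory (floor 2, ceiling
  130 kg N ha⁻¹, midpoint 1995, steepness 0.10 yr⁻¹) × a per-district
  factor × multiplicative log-normal noise (σ = 0.05; σ = 0 puts the
  series exactly on the curve);
* 8 crops (3 legumes) with fixed district area shares of GCA and linearly
  growing yields (0.55 → 2.2 × base yields over the span, which places the
  national mean surplus near 20 kg N ha⁻¹ at the start and ~100 at the
  end, the classic intensification trajectory); GCA/NCA ∈ [1.1, 1.8];
  cropland area equals NCA by construction;
* livestock only at quinquennial census years, so the pipeline's
  interpolation is always exercised;
* a smooth deterministic deposition field (1.9° × 2.5°, monthly 1966–2014,
  base 5 kg N ha⁻¹ yr⁻¹ with a latitudinal gradient and a small positive
  trend, disaggregated by fixed monthly weights with a monsoon peak) and a
  finer 1.0° annual manure grid ending 2014 — two different regridding
  resolutions and both extension paths are exercised.

Everything is deterministic given `rng_seed`. What the generator does
**not** emulate: district boundary changes, reporting gaps and revisions,
correlated measurement error, real spatial covariance of deposition, or
crop-mix shifts over time. Passing tests therefore demonstrate the
*accounting machinery* — unit handling, method wiring, conservation,
ensemble spread — not the realism of any coefficient.

The bundled coefficient tables (N contents, %Ndfa/NHI/BGN, excretion
rates, TAM, fate fractions) are documented placeholders of
literature-plausible magnitude; real analyses must supply their own tables
through the same CSV schemas.

`ground_truth_surplus` recomputes any member with straight-line loops that
share no code with the pipeline (own haversine, own interpolation, own
sums); `collapsed_bundle` builds a control input on which all 12 members
coincide and the spread must vanish identically.

## Numerical choices and edge cases

* Missing coefficients: policy `skip` (default) excludes the crop/category
  with a warning — mirroring budgets restricted to a listed crop set —
  `error` raises naming the key.
* Zero basis area with a nonzero load is flagged per the same policy
  (dropped with a warning, or an error); zero load over zero area is 0.
* Registry loads validate ranges up front: fractions in [0, 1],
  `AM_CN + AM_CL + AM_FL ≤ 1`, N content in [0, 0.2), production-system
  shares summing to 1 within 1e-9.
* Panel validation collects structured violations (negative areas,
  GCA < NCA, duplicate keys, off-grid census years, production without
  harvested area, years outside the configured span); fatal reports raise
  with the first 50 entries.
* Output CSVs are written at 6 significant digits, making re-runs
  byte-identical and round-trips stable; derived checks use relative
  tolerances accordingly.
* The district-to-cell assignment tie-break ((lat, lon) index order) is
  deterministic and matched exactly by the brute-force oracle used in
  tests.

## Problem sizes

The shipped tests and the acceptance script run the default 25-district ×
52-year scenario for ensemble-level checks and 6–10-district, 12–15-year
bundles for the oracle-recovery sweeps; these sizes exercise every code
path (census interpolation, both grid resolutions, both extension rules,
all four aggregation schemes) while keeping the full suite in the
tens-of-seconds range.

## Known limitations

* Nearest-neighbour regridding only; no area-weighted/conservative
  remapping of the deposition or manure grids.
* Whole-district region assignment; fractional (area-split) mappings are
  representable in the schema but not generated.
* No pasture manure, no free-living fixation, no crop-specific fertilizer
  allocation — the budget is a cropland soil-surface balance.
* The ensemble is equal-weight by construction; members are alternative
  methods, not draws from a calibrated error model, so IQR/sd quantify
  methodological spread rather than calibrated uncertainty.
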