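# Methods

This note documents the models implemented in `pfsmoke`, the synthetic
study that exercises them, and the numerical and design choices behind
both.

## The estimation framework

### Burned-area calibration

Satellite fire products have a minimum detectable burn size (default
1.18 acres here, versus 0.03 acres in permit records) and systematically
over-report the area of detected burns. Where a permit system keeps
complete records, gridded daily permit area can be regressed on gridded
daily satellite area and the slope used as a region-wide scaling factor.

Choices:

* **Pairing key** is (grid cell, date). No cross-date or adjacent-cell
  matching is attempted.
* **Through-origin fit by default** (`fit_scaling(..., fit_intercept=False)`):
  the calibration is a single scaling factor. A free intercept is a config
  switch.
* Keys with positive satellite area and zero permit area are **retained**
  — discarding unmatched satellite detections would bias the slope upward.
  The converse (permits with no detection) cannot be paired, because the
  satellite record is the quantity being calibrated.
* Calibration is only meaningful **where permit reporting is complete**.
  With permits missing at random event level, every undetected permit
  enters as a false zero and the fitted slope estimates
  (coverage × true factor) instead of the true factor. The synthetic
  permit record therefore supports a region-structured coverage mode
  (complete inside a block of grid columns, absent outside), and the
  pipeline fits the calibration inside that region only — mirroring how
  such calibrations are done against the subset of jurisdictions with
  complete records.

### Emissions

`emission = area × fuel_load × consumption_fraction × EF / 1000` (tons),
with EF in g per kg of fuel consumed. A single uniform fuel type with
complete consumption of fine fuels is assumed; there is no combustion-
phase split, plume rise, or diurnal profile. Defaults (fuel load
24.7 t/acre, consumption 1.0, total PM2.5 EF 30 g/kg) are anchored so a
prescribed burn emits ≈0.74 t PM2.5 per acre, the per-acre rate regional
inventories imply for southeastern prescribed burning. Component EFs
split that total so EC carries 13% and OC 46% of emitted PM2.5 mass
(EC 3.9, OC 13.8, NO3 0.6, SO4 1.2, OTHER 10.5 g/kg).

### Zero-out attribution

The PF-attributable field is the pointwise difference of the paired runs.
Negative deltas are **preserved, not clamped**: under nonlinear chemistry
a source's removal can locally raise a species, and flooring the
difference would silently destroy mass consistency. An optional clamp
exists at the aggregation stage (`clamp_negative`, default off).

### Data fusion

Total PM2.5, per day:

1. fit a polynomial (degree 2 by default) mapping simulated to observed
   values over collocated monitor pairs; days with fewer than
   `min_pairs_per_day = 5` pairs fall back to a pooled fit over the whole
   period. Outside the fitted range the polynomial is extended
   **linearly** with its boundary slope (floored at 0) — a quadratic
   extrapolated to plume maxima far above anything seen at monitors would
   be wild;
2. at each monitor compute the residual ratio observed/corrected and
   interpolate the **log** ratios over the grid by inverse-distance
   weighting (power 2) with weight `max(0, 1 − d/R)/d^p`, which tapers the
   correction to ratio 1 beyond `R = 300 km` and reproduces each site's
   ratio at its own cell; multiply;
3. floor at `concentration_floor = 0.01 µg/m³`.

Species are fused through **species-to-total ratios**, not absolute
concentrations: per species, the correction observed-ratio/simulated-ratio
is computed at speciation monitors on their sampling days (observed ratios
use the same sampler's total), gap-filled **linearly in time** across each
site's 1-in-3-day schedule (held constant beyond its endpoints),
interpolated in space as above, applied to the simulated ratio field,
clipped to [0, 1], and the vector {EC, OC, NO3, SO4, OTHER} renormalized
to sum to one. Fused species concentration = fused ratio × fused total, so
components sum to the fused total **exactly**, by construction. OTHER is
defined by subtraction so the budget closes; a negative OTHER is clipped
to 0 before renormalization.

Observation-adjusted PF impacts scale the simulated impact by
fused/simulated concentration, with the denominator floored at
`denom_floor = 0.01 µg/m³` and the multiplier capped at `ratio_cap = 10`
(near-zero simulated concentrations would otherwise inflate impacts
without bound). The same cap is applied to the interpolated residual and
ratio corrections themselves — a package choice extending the cap's
rationale to every multiplicative correction. Wherever floor and cap are
inactive the adjustment preserves the simulated PF *fraction* exactly.

Near-road monitors are excluded before any fusion step: they sample local
traffic plumes unrepresentative of a 12 km cell and would bias the fused
surface high.

The exact functional form of published fusion schemes of this family is
not uniquely specified; the implementation here isolates every such choice
behind `FusionConfig` (degree, pooling threshold, IDW power and radius,
floors and caps).

### Evaluation

`compute_stats` reports n, MB, RMSE, NMB, NME (normalized by summed
observations), MNB, MNE (per-pair normalized, restricted to observations
≥ 1 µg/m³ to avoid division blow-up) and squared Pearson correlation.
Benchmark flags implement the standard photochemical PM2.5 tiers:
goals |NMB| ≤ 10%, NME ≤ 35%; criteria |NMB| ≤ 30%, NME ≤ 50% (all
configurable).

Cross-validation partitions **sites**, not observations, into k folds
(default 10): the fusion interpolates spatially, so record-level folds
would leak the withheld site's own observations into its prediction. For
each fold the fusion is refit without the fold's observations and compared
to them at the withheld sites' cells.

### Aggregation

Coverage weights are exact polygon-rectangle intersection fractions
(planar geometry in grid km coordinates; a projection hook would be needed
for real geodesic data). Regional daily means are area-weighted by
fraction × cell area. Seasonal/annual summaries report mean, sample SD and
median of the daily means per (year, season) stratum; multi-year seasonal
summaries pool daily means across years rather than averaging yearly
summaries; empty strata are NaN, never zero. Period PF shares are ratios
of period means (not means of daily ratios). Exceedance statistics count
grid-cell-days at/above a threshold (default 3.5 µg/m³, 10% of the 24 h
PM2.5 standard) and days whose regional mean exceeds it.

## The synthetic study

The generator's defaults define a desk-scale study emulating roughly one
tenth of a 12-state southeastern-US domain:

| parameter | default | rationale |
| --- | --- | --- |
| grid | 30×30 cells, 12 km | regional CTM resolution at desk scale |
| period | 120 days from 2020-09-15 | touches all three burning seasons (a contiguous 120-day window can only do so across the Sep–Jan boundary) |
| seasonal area weights | JFMA 0.541, MJJAS 0.221, OND 0.238 | observed seasonal split of prescribed burned area |
| events | Poisson, 10/day | ≈4.1 M acres/yr scaled to the domain share |
| areas | log-normal, median 50 acres, σ_ln 1.2 | positive, heavy-tailed, permit-record character |
| burn type / ownership | 70% prescribed, 84% private | detection-classification and ownership splits of the emulated region |
| satellite degradation | min 1.18 acres, miss 20%, area ÷ 0.66 | detection floor and systematic over-reporting |
| permit coverage | 0.5, region-structured | some jurisdictions keep complete records, others none |
| backgrounds (µg/m³) | EC 0.18, OC 1.30, NO3 0.30, SO4 1.30, OTHER 2.92 (total 6.0) | ambient component levels consistent with PF ≈ 8% of ambient PM2.5 at ≈0.5 µg/m³ |
| kernel | Gaussian σ 18 km, wind drift SD 24 km/day | smooth overlapping plumes at 12 km resolution |
| ventilation depth | 12 000 m | single constant folding mixing height and day-scale ventilation; sized so regional-mean PF–PM2.5 is a few tenths of a µg/m³ with plume maxima of tens of µg/m³ |
| model biases | PM2.5 0.80, EC 0.71, OC 1.42, NO3 0.90, SO4 0.79, OTHER 0.85 | species-level systematic CTM biases (OTHER interpolated, unreported) |
| model error field | exp(δ), σ 0.30, 100 km correlation, AR(1) 0.8, mean one | see below |
| monitors | 36 total-PM (daily) + 12 speciation (1-in-3-day), 10% near-road | denser than the emulated network's per-area density, so site-held-out folds and ratio fusion are statistically meaningful at this size |
| observation noise | 10% multiplicative, unbiased, floored at 0 | typical monitor measurement error |

The toy forward model is linear in emissions, conserves emitted mass on
the domain (kernels normalized over the grid), and computes total PM2.5 as
the sum of the five component fields, so species closure holds exactly in
truth fields. Each day's field depends only on that day's emissions: no
carry-over, chemistry, or deposition.

**Why the model fields carry a structural error.** "Model" fields are
truth × species bias × one shared smooth multiplicative error field
(log-normal, spatially correlated, temporally persistent, rescaled to mean
one so the species factors alone set the mean bias; both scenario members
share it, as paired zero-out runs share meteorology). A purely uniform
bias would leave the model perfectly correlated with the truth — then no
fusion could raise held-out R² against independent observation noise, and
a model biased only low could essentially never overestimate the PF impact
above an observed total, making the physical-consistency diagnostic
vacuous. Real transport-model errors are spatially and temporally
coherent; the smooth field supplies exactly the kind of error that fusion
can (and should) correct from neighbouring monitors.

**What passing tests do and do not show.** The generator has no
meteorological realism, chemistry, deposition, plume rise, or
representativeness error; observations are unbiased by construction, and
model error is multiplicative and smooth. Tests on this fixture therefore
demonstrate that the *pipeline machinery* is correct — calibration
recovers a known factor, fusion removes known biases and improves held-out
error, mass balance and PF-fraction preservation hold, aggregation
arithmetic is exact — not that the method would achieve any particular
accuracy on real monitoring data, where error structure is richer and
observation/model mismatches include representativeness effects the
fixture does not model.

## Numerical choices and degenerate inputs

* All randomness flows through numpy `default_rng`; the pipeline derives
  per-stage seeds from one global seed via `SeedSequence`, so runs are
  bit-reproducible and stages can be rerun independently.
* Polynomial fits reduce their degree when there are fewer distinct
  abscissae than degree + 1, falling back to a through-origin ratio when
  all simulated values coincide.
* IDW distances are floored at 1 m to make a site's own-cell weight finite
  but dominant; sharing a cell between two monitors averages their log
  corrections.
* Simulated ratios below 1e−6 are treated as signal-free: corrections are
  computed against the floored ratio, and a renormalization falling below
  it yields equal shares.
* Degenerate inputs raise typed errors rather than returning silently:
  zero usable fusion pairs, no speciation observations, all-zero satellite
  areas, empty polygon intersections, zero ambient means.
* Statistics needing at least two pairs (or two sites per fold) enforce
  their preconditions explicitly.

## Known limitations

* Planar geometry throughout; real-data use needs a projection layer.
* One fuel type and one emission-factor set; no per-cell fuel maps.
* The satellite generator has no false detections (commission errors):
  every satellite event descends from a truth event. The calibration
  therefore never sees spurious detections.
* Temporal gap-filling of speciation corrections is linear; no
  periodicity or covariate structure.
* The fusion produces no uncertainty fields.
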