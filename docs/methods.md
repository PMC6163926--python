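# Methods

## Model

The package measures a person's exposure to a scheduled point-feature
environment (here: BMI-unhealthy food outlets) as a time-integral rather
than a map overlay. Three constructs carry the method:

**Environmental context cube.** Space-time is discretised into voxels
(cell_size × cell_size meters × slot_minutes). For a given day type and
time slot, every outlet whose operating interval covers the slot start
contributes a distance-decay surface evaluated at cell centroids, and the
layer is the sum of those surfaces (superposition). Day types are weekday,
Saturday and Sunday, because business schedules are stratified that way.
Cubes are built natively at 30-min resolution (48 layers) and refined to
10 min (144 layers) by per-pixel linear interpolation between temporally
adjacent layers, wrapping 23:30 → 00:00 to respect the daily periodicity
of schedules. Refinement therefore adds temporal sampling density, not new
information: the 10-min cube is a deterministic function of the 30-min
cube. A cube is flattened to a point cloud with one point per voxel at
(cell centroid, slot midpoint).

**Individual space-time tunnel.** The exposure space is the region swept
by a horizontal disc of radius `Br` following the trajectory: at each
instant with a recorded or imputed position, the tunnel covers the disc
centred there. There is no buffering along the time axis — a metric ball
mixing meters and minutes is dimensionally undefined — and instants inside
unimputed gaps (an hour or longer) are not covered.

**Exposure index.** A cloud point (x, y, t) is intersected on a valid day
iff the participant's position at minute-of-day t that day lies within
`Br` of (x, y). Voxels revisited on different days accumulate (exposure is
repeatable). The index is

    ECEI = sum_i EC_i * W_i / T

with T the participant's total valid observation time in hours on days of
that day type. Per-day-type indices are combined into one value per
participant and method as a valid-day-weighted mean. Indices are z-scored
across the cohort (sample sd, n−1) before entering any model, which makes
the comparison invariant to the decay functions' different value scales.

### Assumptions

- Planar Euclidean geometry in a single projected CRS in meters; adequate
  at county scale, no road-network distances.
- Civil, timezone-naive local time; business hours and day types are
  civil-time concepts.
- An outlet's influence is isotropic, stationary within a time slot, and
  additive across outlets.
- Exposure accrues only while the person is observed (recorded or imputed
  minutes); unobserved time contributes neither exposure nor denominator.

## Parameters

| parameter | unit | default | rationale |
|---|---|---|---|
| cell sizes | m | 100, 150, 200 | the resolution menu under study |
| slot lengths | min | 30, 10 | native build and refined resolution |
| KD bandwidth h | m | 1000 | walkable-influence scale; quartic kernel normalised to integrate to 1 |
| ISDD scale d0 | m | 100 | half-influence distance; bounded form 1/(1+(d/d0)²) avoids the 1/d² singularity while matching inverse-square behaviour for d ≫ d0 |
| NEDD scale d0 | m | 500 | e-folding distance of exponential decay |
| Br | m | 100 | effective range of environmental influence around a moving person |
| weight mode | — | constant | W_i = 1; velocity mode (1/2)^v available, v in m/min |
| validity | — | ≥480 min/day; ≥5 weekdays + 2 weekend days | minute-epoch GPS wear-day conventions |

No published value exists for the decay scales or kernel type; these
defaults are recorded in the run configuration, exposed in `StudyConfig`,
and the downstream z-scoring makes between-method comparisons insensitive
to their absolute scale.

## Numerical and design choices

- **Imputation thresholds are strict**: endpoint distance < 30 m →
  stationary fill at the earlier fix; otherwise gap < 60 min → linear
  interpolation; gaps of 60 min or more are never imputed, regardless of
  endpoint distance (so overnight device-off periods at home stay holes).
  Exactly 30 m interpolates; exactly 60 min stays missing. Imputed minutes
  count toward the 8-h validity rule.
- **Velocity** is m/min between consecutive 1-min fixes (first record 0);
  an interpolated instant carries the velocity of the segment containing
  it. Stationary fills have zero velocity, linear fills constant velocity.
- **Overnight hours wrap**: an interval with close < open contributes
  [open, 24:00) to its own day type and [00:00, close) to every day type
  that can immediately follow it on the calendar (weekday → weekday and
  Saturday; Saturday → Sunday; Sunday → weekday).
- **T (the exposure denominator)** is total valid observation hours of
  that day type, making the ECEI an exposure rate per observed hour and
  well-defined even when the intersection is empty. The alternative
  reading — the temporal span of the intersected points — is implemented
  behind `t_mode="span"`.
- Layer values below 1e-9 are snapped to 0 to keep rasters sparse; the
  cutoff is recorded in layer sidecars.
- Grid cells are half-open squares indexed row-major from the south-west;
  values are sampled at cell centroids (matching the voxel-centroid point
  cloud), not area-averaged.
- The trajectory buffer (GTB) simplifies the polyline by Douglas-Peucker
  at radius/20 before buffering (boundary error ≤ 5% of the radius,
  negligible against Br and far below the variance of GPS jitter) and
  polygonises arcs at 64 segments per circle (area error < 0.2%).
  Ellipses use 256 vertices.
- The standard deviational ellipse uses the principal-axis orientation
  θ = ½·atan2(2Sxy, Sxx − Syy) on centred scatter moments with sample
  (n−1) axis standard deviations; "two standard deviations" is literal 2σ.
  Several SDE conventions exist; this one is rotation-equivariant and
  stated here because no single canonical form is universal.
- Static comparators deliberately ignore business hours — that temporal
  blindness is precisely what they are in the comparison to demonstrate.
- Logistic models: age bands 18–30 (reference) / 31–65 / 65+, male and
  below-college as references. The LR χ² is taken against the
  intercept-only null (one whole-model test per model;
  `null_model="covariates"` tests the exposure term alone). Nagelkerke R²
  rescales Cox-Snell by its maximum. A quasi-separated *nuisance* dummy
  (e.g. a near-empty age band: the emulated cohort has ~2% seniors, one
  person at n = 46) is dropped from adjustment with a note and the model
  refit; separation on the exposure term itself flags the model and
  withholds the odds ratio. No multiple-testing correction is applied
  across the 22 models; raw p-values are reported.

## What the synthetic generator emulates — and what it does not

The generator reproduces the *structure* the framework consumes: ~80
outlets clustered along two road corridors with category-typical hours
(24-h convenience stores, 10:00–22:00 fast food, early bakeries, overnight
pizzerias, and short lunch windows offset per outlet in 10-min steps so
fine temporal resolution genuinely matters); 46 participants × 14
consecutive days (10 weekdays, 2 Saturdays, 2 Sundays) of 1-min positions
following home → work → errand anchor routines with bounded speed, meter-
scale jitter and all three dropout classes; covariates drawn from a
predominantly female, mostly 18–30, half-overweight adult cohort; and
overweight drawn from a logistic model whose true exposure is the
ISDD/100 m/10 min ECEI (β_exposure = 1.5 per SD, chosen to give a strong
but not deterministic effect at n = 46).

It does **not** emulate road networks, transport modes, activity types,
seasonal change, or spatially correlated GPS error. Passing tests
therefore demonstrate that the machinery is correct and that the method
comparison behaves as designed under known ground truth — not that any
particular decay law fits real behaviour.

A consequence worth stating plainly: because the 10-min cube is a linear
interpolation of the 30-min cube, the two exposures are nearly collinear
across participants (r ≈ 0.9999 in the default scenario). At a cohort of
46 the AIC contest between the generating measure and its 30-min parent is
close to a coin flip; the generating *family* (ISDD at 100 m) dominates
the ranking far more reliably than the exact resolution does.
Distinguishing the resolutions by AIC would need cohorts orders of
magnitude larger (roughly n ≳ 1/(1−r²)).

## Problem sizes

Default study conditions: a 3 km × 3 km extent (divisible by all three
cell sizes; 30 × 30 cells at 100 m), 80 outlets, 46 participants, 14 days.
The full menu — 54 cubes, 22 exposure measures, 22 logistic fits — runs in
about half a minute on one CPU; the acceptance script, which adds 50
outcome replicates of the 22-model comparison, in about a minute. Oracle
tests run brute-force checks at up to ~4 × 10⁴ cloud points × 2 days.

## Known limitations

- Euclidean decay only; no anisotropy, no network distances.
- Business hours are deterministic weekly schedules; holidays and
  irregular closures are not modelled.
- The ECEI treats all intersected voxels of a day type alike; activity
  type (working vs. eating at the same location) is not differentiated.
- Associations from the model harness are descriptive; nothing here
  supports causal claims.
- The GeoJSON/GPX readers assume lon/lat input with a local tangent-plane
  projection configured; large study areas should supply pre-projected
  planar coordinates.
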