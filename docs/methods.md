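# Methods

This note documents the models, conventions, numerical choices, and known
limitations of `driftshift`, in the order data flows through the pipeline.

## Checklist filtering

The effort filter applies six rules in a fixed order, each a pure predicate
except the two deduplications:

1. `complete` — keep only complete checklists (observer reported every
   species detected), the prerequisite for treating non-detection as
   information.
2. `protocol` — keep stationary checklists, or traveling checklists with
   strictly less than 5 km travelled. Traveling checklists with missing
   distance are removed (the bound cannot be verified).
3. `unique_location_date` — keep one record per exact (latitude, longitude,
   date) key so heavily surveyed sites are not over-weighted. Coordinates
   are compared exactly as parsed, with no rounding tolerance. The default
   key includes species (one record per species per site-date); a
   per-checklist variant keeps all rows of the single surviving checklist.
4. `observers` — at most 10 observers (inclusive).
5. `group_duplicate` — at most one checklist per sharing group.
6. `duration` — at most 5 h (inclusive). Missing durations are removed by
   default for the same verifiability reason as rule 2.

Both deduplications break ties by keeping the lexicographically smallest
checklist id. This makes the surviving set a deterministic function of the
row *set*, independent of file order — the property the order-insensitivity
tests assert. The attrition report records removals per rule in application
order; because later rules see only earlier survivors, the report is
order-dependent even though the final survivor set (for the pure rules) is
not.

Presence-only "X" counts survive filtering but are excluded from
abundance-weighted centroids by default: a presence-only record carries no
defensible weight. An `as_one` policy (recode X as count 1) is available
behind a flag; it changes centroids only when X records are numerous and
spatially biased.

## Periods, centroids, and the shift statistic

The season is Jan 1–Feb 28; leap days are dropped at ingest so period
assignment is total on the remaining dates. The early window is Jan 1–Feb 6
(37 days), the late window Feb 7–28 (22 days), both inclusive.

The distribution summary is the abundance-weighted arithmetic mean of
geographic coordinates (the "center of mass" convention of wintering-
distribution studies built on crowd-sourced counts). A 3-D unit-vector mean
is available for longitude-wrap safety, but conterminous-US data never
straddle the antimeridian and the two agree to well under 0.01° at flyway
extents, so the arithmetic mean is the default and the one all tests pin
down (to 1e-12 relative against a compensated-summation oracle).

The shift statistic is the great-circle (haversine) distance between the
early and late centroids on a sphere of radius 6371.0088 km (IUGG mean
radius, fixed for backend-independent determinism), signed by the
latitudinal direction of the move: positive north, negative south, zero when
latitudes coincide. Sign from latitude with magnitude from the full
great-circle distance reconciles a north–south reading of results with a
distance-based definition; note the magnitude therefore includes any
east–west displacement. Both the signed and unsigned versions are computed;
signed is the model response.

GPS centroids support two weightings: the plain mean of fixes, and the mean
of per-region (deployment state) centroids weighted by each region's share
of fixes. The two are algebraically identical when the weights are the fix
counts — both are kept because "weighted by frequency of locations per
state" admits both readings, and the identity is itself a useful test.

Flyway assignment is point-in-polygon (`shapely.covers`, so boundary points
are inside) against named GeoJSON polygons; polygons must be pairwise
non-overlapping (shared edges are fine), and boundary points go to the first
containing flyway in the canonical order Atlantic, Mississippi, Central,
Pacific — a deterministic tie-break for a measure-zero event. The Mallard
GPS comparison band restricts to 32.5° ≤ lat ≤ 37.5° N, inclusive.

## Severe-February classification and the two designs

A February is severe when the fraction of conterminous-US grid cells with
temperature anomaly ≤ −4 °C strictly exceeds 0.15. Both boundary semantics
are read literally: a cell at exactly −4 °C is cold; coverage of exactly
15 % is not severe. The fraction is cell-count based by default and
area-weighted when the grid supplies cell areas (the criterion is stated in
area terms, but without a grid specification cell counting is the honest
default; the two coincide on equal-area grids). The decision is monotone in
both the threshold and the required fraction, which a property test asserts.

Two designs feed the model:

* **ece2021** — isolates the February 2021 polar-vortex event: years 2015
  and 2019 (themselves abnormally cold) are removed, and the event indicator
  is true only for 2021. Fit continentally and per flyway (each flyway model
  fit independently, including its own year intercepts).
* **severe_feb** — all years retained, the indicator follows the
  severe-February classification (2015, 2019, 2021 in the default span),
  continental scope only.

Design construction is pure subsetting and labeling; responses are never
altered. Year labels outside the span covered by supplied anomaly grids are
user inputs, not computed claims.

## The hierarchical shift model

Response: signed shift Δ (km) of one species × year × scope cell. Mean
structure: foraging strategy (reference generalist) crossed with the event
indicator (reference non-event), plus a Gaussian random intercept per year
and Gaussian residuals. Fixed effects are dummy-coded with pinned reference
levels, so β₀ is the generalist non-event cell mean and the generalist ×
non-event marginal equals the β₀ draws exactly (asserted as an identity).

**Priors.** Normal(0, 2.5) on the standardized-response scale for all
fixed effects — the autoscaling convention behind "vague" defaults in
applied Bayesian regression software. The package standardizes the response
internally ((y − ȳ)/sd y), samples, and back-transforms, which makes the
intercept prior normal(ȳ, 2.5·sd y) and each coefficient prior
normal(0, 2.5·sd y). A literal N(0, 2.5 km) prior would be absurdly
informative for ~100-km effects. σ_year and σ_ε get half-normal(2.5) priors
on the same standardized scale: weakly informative, positive support,
matching the corresponding software defaults in spirit. A by-product is
exact shift-equivariance — adding a constant to every response moves every
cell median by that constant and leaves interval widths untouched — which
the tests exploit.

**Sampler.** The model is conditionally conjugate, so a blocked Gibbs
sampler is both simple and efficient: the fixed-effect vector has a
multivariate-normal full conditional (6 × 6 Cholesky solve), the year
intercepts have independent normal full conditionals, and the two scale
parameters are updated by univariate slice sampling (stepping-out with
shrinkage) on log σ, where the half-normal prior is handled exactly. Slice
sampling needs no tuning and cannot reject, which keeps the degenerate
flat-response case (zero variance) finite and crash-free; log σ is clamped
to ±15 on the standardized scale as a numerical guard. Chains are seeded
from a single spawning seed sequence; chain inits are overdispersed
(standard-normal coefficients, log-normal scales).

**Settings.** Desk-scale default: 3 chains × 3,000 iterations with 1,000
warmup (2,000 kept draws per chain, thinning 1); full-scale settings
(3 × 10,000, 5,000 burn-in) via `ModelSpec.full_scale()`. With 3,900
records a default fit takes roughly a second on one CPU, which is what makes
the replicated recovery studies routine.

**Convergence.** Per-parameter split-R̂ (each chain halved; R̂ =
√((n−1)/n + B/(nW))), accepted at max R̂ ≤ 1.10. The implementation is
cross-checked against an independent library computation to 1e-8 and against
the textbook formula to 1e-10. Non-convergence never passes silently: the
estimator flags it with a warning and `converged_ = False`.

**Marginal summaries.** Cell values are per-draw linear predictors with the
year intercept marginalised at its population mean (0) — the marginal-means
convention for random intercepts; averaging over realised years is the
config alternative. Summaries are direct quantiles: median, central 66 %
(17th–83rd percentile) and 95 % (2.5th–97.5th) intervals, so nesting is
structural rather than asserted.

**Identifiability caveat.** In the 2021-event design the event indicator is
perfectly collinear with the 2021 year intercept; the two are separated only
by the prior on σ_year, so the event effect's credible interval is honest
but wide. Recovery/coverage studies therefore use the severe-February
layout (three event years among thirteen), where the contrast is informed by
replication. Coverage is evaluated per (replicate, parameter): each of the
six fixed effects' 95 % intervals should cover its truth ~95 % of the time;
a joint all-six-covered event would have nominal rate 0.95⁶ ≈ 0.74 and is
not the quantity checked. The null-recovery check (all effects zero, unit
residual noise) uses 600 records per cell so the ±0.2 km bias bound sits at
~2.4 standard errors of the data-driven contrast noise; at much smaller
sizes the bound would measure the simulated data, not the sampler.

## Synthetic data: what it emulates and what it does not

The generators define the study conditions for all tests:

* **Checklists.** Observation positions scatter isotropically (Gaussian in
  km, converted to degrees at the centroid latitude; default sd 150 km)
  around per-cell true centroids, which keeps the true centroid well-defined
  and analytically recoverable. By default the true centroids are tied to
  the same effect sizes the model is asked to recover: the late centroid
  sits the strategy × event cell-mean shift north of the early one
  (generalist non-event 143 km; grubbing +43 km, wetland obligate −86 km;
  event −85 km with interactions −115/+11 km; σ_year 25 km, σ_ε 120 km —
  continental-scale magnitudes). Counts are negative-binomial (mean 20,
  dispersion 1 — overdispersed, as waterfowl flock counts are), with a 5 %
  presence-only rate so the X-handling paths face real traffic. Filter-rule
  violations are injected per rule as independent Bernoulli marks;
  duplicate- and group-violations are wired to a clean partner with a
  smaller checklist id so the deterministic tie-break removes the violator.
* **GPS.** Default deployment mirrors the 2021 telemetry effort (84
  Arkansas, 210 Tennessee birds); per-bird activity centres scatter 30 km
  around state centres, fixes 5 km around the centre at a 6-h cadence
  (hourly cadence is configurable; the default is sparser at desk scale),
  with an
  optional northward late-window displacement as ground truth.
* **Anomaly grids.** An elliptical pseudo-continent mask with an *exact*
  count of cold cells — `round(fraction × n_masked)` — so classifier
  boundary semantics are testable to the cell.
* **Shift records.** Drawn directly from the model equation with recorded
  truth (including realised year intercepts), for recovery and coverage
  studies.

Not emulated: observer spatial bias beyond configured scatter, phenology
within windows, spatial autocorrelation of observations, detection
probability as a function of effort, or realistic anomaly-field spatial
structure. Passing tests therefore demonstrate correctness of the
*computations* under a known observation process, not robustness of the
scientific conclusions to citizen-science biases — that is what the GPS
cross-validation pathway is for on real data.

All randomness flows from one seed through fixed spawn keys per table, so
identical configs give byte-identical tables regardless of generator call
order.

## Pipeline and provenance

The six stages (simulate → filter → centroids → classify → fit → report) run
from one YAML config; every stage's inputs and outputs are content-hashed
into `manifest.json` together with the seed and package version. All stages
are deterministic given the config; the MCMC stage is additionally
deterministic given its seed and this sampler implementation. Anomaly grids
travel as flat netCDF (scipy backend); posterior draws as JSON (text,
lossless floats); everything else as TSV/CSV/GeoJSON.

## Known limitations

* The signed-distance response conflates east–west displacement into the
  magnitude; with sparse cells (few observations per period) longitudinal
  sampling noise inflates |Δ|, and continental centroids pooled across
  flyways are especially sensitive. Real-data applications should check
  per-cell sample sizes (reported as `n_early`/`n_late`).
* The severe-February classifier depends on the grid and mask supplied;
  cell-count and area-weighted fractions differ on non-equal-area grids.
* The 2021-event design cannot separate the event effect from the 2021 year
  intercept (see above); inference there leans on the prior for σ_year.
* Flyway polygons bundled by the generator are simplified longitudinal
  bands, not administrative boundaries; real analyses must supply real
  polygons.
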