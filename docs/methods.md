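# Methods

`rspfit` estimates how large mammals select resources from scat-survey
use-availability data, and ships a synthetic-data generator so the whole
analysis can be exercised and validated without any field data. This note
documents the models, the generator, the numerical choices, and the known
limitations.

## The estimation problem

A survey walks transects inside square search quadrats and records the
locations where scats (or burrows) of a species are found. These *used*
sites are contrasted with *available* sites — random locations constrained,
like the detections themselves, to within 30 m of the walked transects — to
ask which landscape conditions the species selects.

Two model forms are supported for the selection function over a covariate
vector `x`:

* **exponential RSF**: `w(x) = exp(x'β)`, a *relative* selection weight.
  Under the use-availability likelihood below, adding a constant to the
  linear predictor changes nothing (the package asserts this to 1e-10), so
  the intercept is not identifiable and is fixed at zero.
* **logistic RSPF**: `π(x) = expit(β₀ + x'β)`, a true selection
  probability in (0, 1) — the probability a resource unit is selected given
  that it is encountered.

Both are fitted by maximizing the weighted-distribution log-likelihood

    ℓ(β) = Σ_{i∈used} log π(x_i; β) − n_used · log( (1/n_avail) Σ_{j∈avail} π(x_j; β) )

in which the availability sample is the Monte-Carlo integration set for the
normalizer of the use distribution. The availability points are an
integration device, not observations; consequently BIC uses `n = n_used`
by default (`bic_n="all"` is available for sensitivity analysis).

### Optimization and uncertainty

Covariates are centered and scaled internally; optimization is BFGS with an
analytic gradient from β = 0 plus five random restarts drawn N(0, 0.5²) on
the standardized scale, keeping the best optimum; coefficients are reported
back on the input scale. Convergence requires a gradient max-norm below
1e-6 (the optimizer's own success flag, or a post-hoc norm below 1e-4, also
counts). A coefficient exceeding 50 on the standardized scale flags
separation. Constant columns are flagged inestimable and pinned at zero;
the other coefficients are unaffected.

Standard errors are square roots of the diagonal of the inverse observed
information, computed as a central finite-difference Hessian of −ℓ at the
maximum with per-coordinate step `1e-5·max(1, |β̂_k|)`. A non-positive-
definite Hessian is flagged and SEs for non-informative coordinates are
reported as undefined rather than invented.

### Weak identifiability of the logistic intercept

A structural property of logistic RSPF estimation, reproduced faithfully
here, is that the likelihood approaches the exponential-form likelihood as
β₀ → −∞ with slopes held fixed. When the data contain few sites with high
selection probability (in our validation study the generating model caps π
at expit(1) ≈ 0.73), a sample may have *no interior maximum*: the supremum
sits on that boundary ridge, the optimizer reports a very negative
intercept, and every predicted probability is near zero. In the package's
own 50-replicate recovery study (below) roughly 10% of replicates land on
this ridge — we verified that starting the optimizer at the true parameters
converges to the same ridge, so this is the likelihood's geometry, not an
optimization artifact. These degenerate fits are exactly what the two-step
selection's anomaly screen (`max_near_zero`) removes in the full pipeline;
the recovery study reports their count (`n_degenerate`) alongside coverage.
The practical consequences: 3·SE coverage for the affected slope sits near
(sometimes just under) 90%, and the intercept's empirical-SD-to-mean-SE
ratio is unstable across study seeds. Slope estimates in non-degenerate
replicates are well calibrated.

## Model selection

Selection is two-step. Step 1 ranks converged candidates by
`BIC = −2ℓ + k·log n_used` (ΔBIC relative to the minimum; unconverged
candidates are excluded with a note). Step 2 walks the ranking and returns
the first candidate whose predicted values pass the anomaly screen:
`max_near_zero` if max(π) < 0.01, `confined` if the P95−P5 spread of π is
below 0.05 (both thresholds configurable; they operationalize a qualitative
screen and have no canonical values). Exponential-form candidates produce
relative weights, not probabilities, so the probability screens do not
apply to them. If every candidate is flagged, the BIC-best is returned with
its flags attached so pipelines complete.

## Covariates

The standard suite has 24 columns: park membership (boundary counts as
inside) and distance to the park in meters; spring within 500 m and road
within 30 m (closed comparisons at the thresholds); distance to rivers in
meters and to roads / main roads in kilometers; eight exhaustive
habitat-class indicators (riparian forest, woodland cerrado, open cerrado,
grassland, marsh, pasture, agriculture, unknown); distances in kilometers
to agriculture, to closed-canopy classes (forest, cerrado) and to any
habitat edge (a cell whose 4-neighbourhood contains a different class);
circular focal-window proportions — closed (forest+cerrado) and natural
(five natural classes) in a 1.4 km² window, open-canopy non-crop
(grassland, open cerrado, pasture) in 1.4 km², non-cropland in 1 km²;
elevation; and a window heterogeneity count.

Choices that the source material leaves open:

* **"1.4 km²" windows.** The covariate definitions give an *area*; other
  passages read as a radius. The default treats the value as an area
  (circular window, radius √(1.4/π) km ≈ 667.6 m); `window_mode="radius"`
  supports the other reading.
* **Heterogeneity windows.** "Small, medium, large" are unspecified;
  defaults are 250, 500, 1000 m radii. The standard 24-column suite uses
  the medium window for its single `heterogeneous` column; per-radius
  columns are available from `heterogeneity()` directly.
* **Focal windows at the study boundary** renormalize over the cells
  actually present (default) or keep the full-disc denominator
  (`pad_zero`).
* Raster distances use the Euclidean distance transform on 30-m cells and
  are exact to within half a cell of a brute-force oracle; focal windows
  are circles centered at the *point* (not its cell center), evaluated over
  cell centers.
* Coordinates are projected planar meters in an arbitrary local frame;
  raster origin top-left; points map to cells by half-open intervals.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
any particular map:

* **Habitat raster** (30-m cells): classes drawn by rank-thresholding a
  Gaussian-smoothed random field (correlation length 600 m), separately
  inside and outside the park, so class proportions match the requested mix
  essentially exactly while classes form spatially clustered patches.
  Default landscape-wide mix (agriculture-dominated matrix with remnant
  natural vegetation): forest 0.06, cerrado 0.08, open cerrado 0.10,
  grassland 0.18, marsh 0.02, pasture 0.16, agriculture 0.37, unknown 0.03.
  Inside the park (default 28% of a 80 × 57.6 km extent) the developed-class
  mass is reassigned to natural classes; the exterior compensates so the
  global mix is preserved. Rivers carry a 60-m riparian-forest buffer.
  "Unknown" cells are spatially clustered like every other class.
* **Vector features**: meandering rivers, straight-ish roads (a subset
  flagged as main roads), springs placed near rivers, a rectangular park,
  and a smoothed elevation surface (mean 800 m, SD 60 m).
* **Survey design**: non-overlapping 5×5 km quadrats (65 by default)
  placed on a candidate lattice; inside each, free-form random-walk
  transects with *exactly* 30-m steps (the GPS-waypoint interval), mean
  length 7.6 km, several per quadrat. Transect routing is necessarily
  invented — the original paths were walked by dog-handler teams.
* **Used points**: rejection sampling from a known selection model over
  the 30-m corridor; candidates are corridor-uniform and accepted with
  probability π/max π over the candidate pool. Contents and age attributes
  are uniform over small categorical sets and exist to exercise
  deduplication.
* **Availability**: arc-length-uniform positions along the transects with
  a uniform perpendicular offset in [−30, 30] m, i.e. uniform over the
  corridor band (20,000 points by default, shared across species).
* **Deduplication**: single-linkage clusters of same-species detections
  with pairwise links under 5 m and identical contents and age collapse to
  the earliest-indexed member. Single linkage is the closure of the
  pairwise field rule for chains; radius and key attributes are
  configurable. The operation is idempotent.
* **Seeding**: one master seed splits into named independent streams
  (landscape, roads, transects, detections, availability…), so any module
  can be regenerated alone, and every operation is a pure function of its
  inputs and seed.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: spatial autocorrelation of detections beyond what the
selection model induces, territorial scat placement, imperfect detection or
effort variation, multi-year dynamics, real road/river network topology,
and classification error structure beyond a generic clustered "unknown"
class.

## Validation studies

`rspfit.studies` defines the two seeded simulation studies the test suite
and the acceptance script share. Both run on a 12×12 km landscape with four
5×5 km quadrats and three ~5 km transects each — large enough for ~70,000
corridor points per replicate yet fast enough for 50 replicates on one CPU
in a few minutes; these sizes are the package's validation design.

* **Parameter recovery**: logistic RSPF with β = (−2, 2, 1) on the closed
  and natural focal proportions; per replicate, 1,000 used points and a
  fresh 20,000-point availability sample; reports per-coefficient 3·SE
  coverage, the empirical-SD/mean-SE ratio, and the degenerate-replicate
  count (see the weak-identifiability section).
* **BIC ranking power**: how often BIC ranks the generating specification
  above one omitting its strong (|β| = 2) covariate; 5,000 availability
  points per replicate.

## Other conventions and defaults

* Quantiles (boxplot summaries) use linear interpolation of order
  statistics, position `1 + p(n−1)`; configurable.
* Binned-proportion summaries use 10 equal-width bins on [0, 1].
* Summaries cover the used sites of a species by default (`all_sites`
  includes availability points).
* Burrow locations enter as used sites through the same pathway as scats
  and are pooled into a single per-species dataset.
* The availability sample is shared across species (a per-species sample
  is available); covariates for a shared available point are computed once
  and identical across species datasets.
* Rasters are read/written as ESRI ASCII grids, vectors as GeoJSON in the
  local projected frame, points as CSV; a JSON manifest records the seed
  and a configuration hash. No real-world CRS handling is attempted.

## Limitations

No detection-probability or effort modelling (detections are assumed
unbiased); no random effects or spatial autocorrelation; Euclidean
distances only; no model averaging or AIC variants; prediction output is
tabular (no map rendering beyond the summary boxplots).
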