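# Methods

## The model

`scrpath` estimates animal density from spatial capture-recapture (SCR)
surveys with binary proximity detectors — detectors that record whether an
individual was detected on each sampling occasion without holding it.  Each
individual `i` is assumed to have a fixed, latent activity center `x_i`.
Detection at detector `k` on occasion `s` is Bernoulli with a half-normal
kernel in the distance between activity center and detector:

    p(x, k) = g0 * exp(-d(x, k)^2 / (2 sigma^2))

- `g0` — detection probability at the activity center, logit-linear in sex
  and in `bk`, a trap-specific learned response: an indicator that the
  individual was already detected at that same detector on an earlier
  occasion within the survey.  `bk` captures, e.g., attraction to a baited
  site after a first visit.
- `sigma` — the spatial scale of movement (metres), log-linear in sex and,
  optionally, in a latent two-class finite mixture (`h2`) with mixing
  proportion `pi` (logit scale).  The mixture absorbs heterogeneity in
  home-range size from unobserved sources.
- Effort: each detector-occasion has a usage `u` in [0, 1]; the realized
  detection probability is `1 - (1 - p)^u`.  This is the
  hazard-proportional form: `u = 0` forbids detection, `u = 1` leaves `p`
  unchanged, fractional effort interpolates on the complementary-log scale.

The likelihood is conditional on each individual being detected at least
once.  The latent activity center is integrated over a habitat mesh — a
lattice of candidate centers at 1 km spacing (default) covering everything
within 15 km of a detector, with cells falling in water removed:

    L_i = [ sum_j pi_j sum_x A Pr(omega_i | x, j) ] /
          [ sum_j pi_j sum_x A pdot(x, sex_i, j) ]

where `A` is the mesh cell area, `Pr(omega_i | x, j)` multiplies the
Bernoulli terms over occasions and detectors (with `bk` read from the
individual's own history), and `pdot` is the probability that a *naive*
animal (`bk = 0`) centred at `x` is detected at least once.  Non-mixture
models are the `pi_1 = 1` special case.  Parameters are estimated by
quasi-Newton (BFGS) maximization with numerical derivatives; the parameter
covariance is the inverse of the numerically differentiated observed
information.

Density is the Horvitz-Thompson style derived parameter

    D = sum_i 1 / a_i ,

with `a_i` the effective sampling area for individual `i`'s sex (the mesh
integral of `pdot`, mixture-weighted).  Its variance assumes activity
centers follow a homogeneous Poisson process: a Poisson component
`sum a_i^-2` plus the delta-method propagation `G' V G` of parameter
uncertainty.  RSE = SE / D.

## Ecological (least-cost-path) distance

Non-Euclidean models replace `d(x, k)` with the accumulated cost of the
cheapest grid path across a resistance surface.  A landscape covariate
(road density, terrain ruggedness from the vector ruggedness measure, or
waterbody density) is block-aggregated to a working resolution, linearly
rescaled to [1, 10] (so resistance coefficients are comparable across
covariates, and no zero costs can occur), and transformed per cell to

    cost = exp(alpha2 * z).

`alpha2 > 0` means the covariate impedes movement; `alpha2 < 0` means it
facilitates movement.  For road-type covariates `alpha2` is estimated on
the identity scale (roads may act as corridors or barriers); for
ruggedness and water it is estimated on the log scale, i.e. constrained
positive, because "facilitation" by rugged terrain or open water is not
biologically credible here.  `alpha2` is estimated jointly with the
detection parameters: every likelihood evaluation at a new `alpha2`
re-solves the shortest-path problem.

The grid graph connects each cell to its 8 queen neighbours plus,
by default, the 8 knight moves (16 directions).  An edge costs the true
step length times the arithmetic mean of the two endpoint cell costs — the
convention of conductance-raster tools, with geometric correction implicit
in the true diagonal/knight step lengths.  With uniform cost the metric
over-estimates straight-line distance by at most 8.2% (8 directions) or
2.8% (16 directions); these bounds are verified numerically in the tests.
Shortest paths are solved by Dijkstra's algorithm on a cached sparse graph
(topology and step lengths built once per raster; only weights are
refreshed when `alpha2` moves), and mesh-to-detector matrices are memoized
on `alpha2` because line searches and finite-difference gradients revisit
nearby values.

Mesh points and detectors snap to the center of the containing raster
cell; ties on cell boundaries go to the lower-indexed cell.  Pairs
separated by nodata are flagged unreachable and contribute zero detection
probability.

### Approximate nesting of Euclidean and lcp models

With `alpha2 = 0` and a flat covariate, the lcp model does *not* reduce
exactly to the Euclidean model: grid-metric anisotropy and cell-snapping
discretize the distances.  The sex-specific `sigma` absorbs the mean
inflation, but a residual log-likelihood offset of order one unit remains,
and it grows with raster coarseness relative to the mesh spacing.  The
likelihood-ratio comparison against the Euclidean base model (as used
throughout the model suite) therefore tolerates a small negative statistic
for cross-metric comparisons (clamped to zero, i.e. "no improvement")
instead of treating it as a failed fit.  The null-calibration test uses
the 480 m resolution, the coarsest grid at which this distortion is small
relative to a 1 km mesh; at 960 m the same test becomes conservative
(rejection rate falls below nominal), which is a property of the
grid approximation, not of the test.

## The candidate model suite

Per survey, 20 models: the base Euclidean model (sex effects on `g0` and
`sigma`, `bk` on `g0`), the Euclidean model plus the two-class `sigma`
mixture, and one lcp model per covariate (roads, ruggedness, water) at
each of six resolutions (30, 60, 120, 240, 480, 960 m).  Complex models
are compared to the base model by likelihood-ratio test at alpha = 0.05
(strict inequality), with the base fit's estimates used as starting
values.  The mixture LRT (df = 2) sits on a boundary of the parameter
space (`pi` at 0/1, class effect at 0); the plain chi-squared reference is
used deliberately, which makes that test conservative.

Filters and inspections applied to fitted models:

- density above 1 animal/km^2 — implausibly high for this system;
- RSE above 40% — too imprecise to be useful (missing RSE counts as a
  failure, conservatively);
- surveys with detections-per-animal (DPA) at or below 3 are dropped
  before mixture/resistance modelling;
- mixture fits are flagged when the majority latent class (by mixing
  weight — per-individual posterior assignment is deliberately not used)
  has `sigma` under 1 km (females) or 2 km (males), movement scales
  smaller than a plausible home range.

## Synthetic data

The generator emulates the structure of a hair-snag black-bear survey:

| quantity | default | rationale |
|---|---|---|
| detectors | 42, curvilinear branching array | arrays of 40-45 along secondary roads |
| trap spacing | 1500 m | slightly under female `sigma` |
| occasions | 5 | weekly sampling |
| `g0` | F 0.15, M 0.10 | low detectability at baited corrals |
| `sigma` | F 2000 m, M 3500 m | females ~2 km, males >3 km |
| density | 0.2 / km^2 | yields DPA in the observed 1.6-5.2 range |
| buffer | 15 km | >4x male `sigma` |
| mesh spacing | 1000 m | half the trap spacing |

Activity centers are drawn from a homogeneous Poisson process on a
continuous rectangle (trap bounding box + buffer) and are *not* snapped to
the mesh, so mesh-discretization error is part of every recovery test, as
in real data.  Mixture class is drawn once per individual.  Landscapes:
roads are biased random walks crossing the grid (connected linear
features), ruggedness is a smoothed Gaussian field on [0, 1], water is a
quantile-thresholded smoothed field giving compact blobs at a target areal
fraction.

What the generator does not emulate: genotyping error and
misidentification, open-population turnover, spatially varying density,
behaviourally realistic movement paths, and real road-network topology.
Passing recovery tests therefore validate the estimator under its own
assumptions, not robustness to these violations.

## Numerical choices

- Links: logit(`g0`), log(`sigma`), logit(`pi`), identity or log
  (`alpha2`).
- Per-individual mesh sums use log-sum-exp; non-detection terms collapse
  to two per-trap effort totals (naive / post-detection), making the
  likelihood cost linear in mesh size and detections.
- Optimizer: BFGS, gradient tolerance 1e-6, max 500 iterations, up to 3
  jittered restarts (sd 0.3 on the link scale) on non-convergence.
  Starting values: `g0` 0.1, `sigma` from the mean within-individual
  maximum detection spread divided by sqrt(2) (floor 200 m, fallback
  2 km); complex models start from the base fit.
- Observed information by central differences (relative step 1e-4);
  a singular or indefinite information matrix is flagged and SE/RSE are
  reported unavailable rather than fabricated.
- Non-finite likelihoods raise (overflow is never silently clamped);
  impossible histories yield +inf, which the optimizer treats as a
  rejected step.
- Degenerate rescale (constant covariate) maps to 1 everywhere: a
  constant surface carries no resistance signal and must not create
  zeros.
- Block aggregation with a factor that does not divide the grid
  aggregates the partial edge blocks over available cells and flags the
  output (`meta['partial_blocks']`).
- VRM uses Horn 3x3 slope/aspect on an odd-reflection-padded DEM, so
  planes (flat or tilted) give exactly zero ruggedness, including at
  edges.
- Every stochastic routine takes an explicit seed; identical seed,
  identical output.

## Problem sizes in the test suite

Statistical tests run at sizes chosen to keep a serial run practical
while leaving the study conditions intact: parameter recovery uses 50
replicate surveys at the default design; null LRT calibration uses 100
replicates on a compact 25-trap grid with a 10 km buffer and the 480 m
roads raster; the heterogeneity-bias comparison uses 30 replicates of a
36-trap grid with mixture truth (`pi` 0.5, `sigma` classes 1 km / 3 km).
Mask-adequacy compares 15 km vs 20 km buffers on one survey.

## Known limitations

- The conditional likelihood cannot estimate density surfaces
  (inhomogeneous Poisson intensities); density is a derived constant.
- Sex must be observed for every individual; there is no hybrid
  sex-mixture support.
- The mixture LRT boundary issue above makes that test conservative.
- Cross-metric LRTs inherit the grid-approximation offset described
  above; at raster resolutions at or above the mesh spacing they are
  conservative.
- `alpha2` estimation re-solves shortest paths inside the optimizer; on
  large rasters (30 m resolution over a full study area) this is the
  dominant cost, as it is in the tools this workflow mirrors.
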