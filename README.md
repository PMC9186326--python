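# scrpath

Spatially explicit capture-recapture (SECR) density estimation for
proximity-detector surveys, with support for **least-cost-path
("ecological") distances** through landscape resistance surfaces and
**finite-mixture detection heterogeneity**.

## Who this is for

Wildlife biologists and biostatisticians estimating population density
from detector arrays that record individual identity — hair snags with
genotyping, camera traps, acoustic arrays — who want to go beyond the
standard Euclidean half-normal detection model: to ask whether roads,
terrain ruggedness, or water bodies shape how far animals range around
their activity centers, and whether latent movement heterogeneity is
biasing their estimates.

## The model

Each individual has a latent activity center `x`; detection at detector
`k` on occasion `s` is Bernoulli with probability

    p = 1 - (1 - g0 * exp(-d(x,k)^2 / (2 sigma^2)))^u

where `g0` (logit scale) depends on sex and on prior detection at that
same detector (`bk`, a learned response), `sigma` (log scale) depends on
sex and optionally a two-class latent mixture `h2`, and `u` is the
per-detector-occasion effort.  `d(x, k)` is either Euclidean distance or
the accumulated cost of the least-cost path across `cost = exp(alpha2 * z)`
for a [1, 10]-scaled landscape covariate `z`, with `alpha2` estimated
jointly in the likelihood (`alpha2 > 0`: the covariate impedes movement).

The likelihood is the conditional likelihood for proximity detectors
(integrating activity centers over a buffered habitat mesh), and density
is the derived parameter `D = sum_i 1 / a_i` with `a_i` the sex-specific
effective sampling area, with asymptotic variances under a homogeneous
Poisson point-process assumption.  Candidate models (2 Euclidean + 18
least-cost-path across 3 covariates x 6 resolutions) are compared by
likelihood-ratio test; implausible fits (density > 1 animal/km^2,
RSE > 40%, small-`sigma` majority mixture classes) are flagged.  See
`docs/methods.md` for the full account.

## Worked example

Simulate a survey at the default design (42 detectors in a curvilinear
branching array at 1.5 km spacing, 5 weekly occasions, true density
0.2 animals/km^2), fit the base model, and test a road-resistance model
against it:

```python
import scrpath as sp
from scrpath.core import ModelSpec

traps = sp.gen_trap_array("curvilinear", 42, 1500.0, seed=1)
data  = sp.simulate_scr(sp.TruthSpec(density=0.2, seed=1), traps, seed=1)
print(sp.capture_summary(data))

mesh = sp.make_mesh(traps, buffer=15_000.0, spacing=1_000.0)
base = sp.fit_model(ModelSpec(), data, mesh, traps)
print(f"D = {base.density:.3f} / km^2, RSE = {100 * base.rse:.1f}%")

roads = sp.rescale_to_1_10(
    sp.landscape_for_traps("roads", traps, 15_000.0, 480.0, seed=2))
lcp = sp.fit_model(
    ModelSpec(distance_mode="lcp", covariate="roads", resolution=480),
    data, mesh, traps, surfaces={("roads", 480): roads},
    start=base.params)
rec = sp.compare_to_base(base, lcp)
print(f"alpha2 = {lcp.params.alpha2:.3f}, LRT p = {rec.lrt_p:.3f}")
```

Output:

```
CaptureSummary(detections=250, individuals=110, recaptures=140,
               spatial_recaptures=125, dpa=2.272727272727273)
D = 0.226 / km^2, RSE = 11.7%
alpha2 = -0.011, LRT p = 0.274
```

The survey detected 110 individuals 250 times; the fitted density 0.226
bears/km^2 sits within sampling error of the true 0.2, with useful
precision (RSE 12%).  The road-resistance coefficient is near zero and
the likelihood-ratio test finds no support for it — as it should, since
these data were simulated with Euclidean movement.

A thin CLI mirrors the library for shell use:

```bash
scrpath simulate --n-traps 42 --density 0.2 --seed 1 --out survey/
scrpath fit --traps survey/traps.csv --captures survey/captures.csv \
            --usage survey/usage.csv --out fit.json
scrpath compare --data survey/ --models euclid --out results/
```

## Layout

- `src/scrpath/raster.py` — covariate rasters: ESRI ASCII I/O, block
  aggregation, [1, 10] rescaling, vector ruggedness measure, exponential
  cost transform
- `src/scrpath/distance.py` — Euclidean and least-cost-path distance
  matrices (cached Dijkstra over 8/16-direction grid graphs)
- `src/scrpath/core.py` — habitat mesh, conditional likelihood, fitting,
  effective sampling area, derived density
- `src/scrpath/suite.py` — the 20-model candidate set, likelihood-ratio
  tests, filters, plausibility checks, delta summaries
- `src/scrpath/simulate.py` — synthetic landscapes, trap arrays, capture
  histories
- `src/scrpath/io.py`, `src/scrpath/cli.py` — survey text formats,
  reports, configuration, CLI
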