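# Methods

This note documents the models and procedures implemented in `fireprogress`,
the choices made where the design was genuinely open, and what the synthetic
study conditions do and do not establish.

## Day-of-burning interpolation

Pixels inside a fire's final perimeter are assigned the day of the nearest
dated detection — 1-nearest-neighbor in planar meters between pixel centers
and detection points, ties resolved to the earlier day so progression is
never pushed later by coincidence. This is the simplest member of the family
of detection-based fire-progression interpolators; the function is a single
entry point (`interpolate_dob`) so k-NN or inverse-distance variants can be
added without touching callers. Detections falling outside the perimeter
still participate in the assignment but generate no burned pixels.

Perimeter rasterization, like every polygon-to-raster step in the package,
uses cell-center containment. Final footprints are polygonized as unions of
full cell squares, so polygonize → rasterize round-trips a mask exactly;
this is what makes the dense-detection round trip (interpolated DOB equal to
simulator truth bit for bit) a meaningful test rather than an approximation.

Fires enter the spread analysis only if they have at least 10 detections and
at least 0.1% aspen inside the perimeter (both bounds inclusive).

## Daily patches and spread metrics

A DOB raster is split, per day, into 8-connected components ("daily
patches") — 8-connectivity is used for patches, adjacency, and the spread
process alike, so no configuration can spread through a boundary it could
not also be connected across. Each patch carries:

- **Daily area burned** (ha): pixel count × (pixel size)² / 10⁴.
- **Maximum daily linear spread** (m): the *shared boundary* is the set of
  patch pixels 8-adjacent to any earlier-burned pixel. For each patch pixel
  the Euclidean distance to the nearest shared-boundary pixel center is
  computed (exactly, via a KD-tree, not a chamfer approximation); the patch
  statistic is the maximum. A patch with an empty shared boundary is
  *discontinuous* (a spot fire or first day); its distances are seeded at
  the day's earliest detection that falls inside the patch, or the patch
  centroid when no same-day detection does (flagged in the output). The
  minimum distance over non-shared pixels is also recorded
  (`min_advance_m`) as the closest-boundary reading of daily advance; it is
  a diagnostic and never enters the models, because the per-patch maximum is
  the value mapped across the whole patch.

## Vegetation classification

Fine vegetation legends are collapsed onto 11 coarse groups (aspen, cool
conifer, disturbed, herbaceous, mixed aspen–conifer, nonflammable, shrub,
warm conifer, wetland, woodland, prior burn) through a two-column CSV
mapping; a synthetic 20-code stub legend ships with the package for demos
(`load_stub_legend`) — a real crosswalk is user data. Areas burned 1–10
years before a focal fire become `prior_burn`; where prior perimeters
overlap, the most recent burn year decides the gap, so a cell re-burned in
the focal year is *not* relabelled even if an older in-window burn also
covered it. Multi-year vegetation layers are selected per fire as the most
recent version preceding the fire year, falling back to the earliest
version for fires that predate them all.

## Covariates

Weather/climate/terrain layers are sampled at 0.1% of each patch's pixels
(minimum one), drawn once per patch from a stream keyed by (fire, day) so
adding patches never reshuffles others, with nearest-cell lookup on the
covariate's own grid — reading a reanalysis cell at a point, not smoothing
it. Monthly climate z-scores standardize a fire-month value against the
pooled April–June monthly values of a 30-year reference window (n = 90),
with the n−1 standard deviation; pooling (rather than a mean of monthly
climatologies) is a documented choice, switchable by passing a different
reference vector. Terrain aspect is circularly transformed to
(eastness, northness) = (sin, cos), with flat cells mapped to (0, 0).

## Statistical models

**Spread models.** Both spread metrics are approximately log-normal, so the
models run on log₁₀ values; zero-spread patches (no-advance days) are
floored at half a pixel (15 m) before the log. Mixed models are Gaussian
with a random intercept per fire, fit by maximum likelihood (not REML) so
AIC comparisons across fixed-effect structures are valid; a fit with
non-finite standard errors or a singular covariance falls back to OLS and is
flagged. Variance explained is reported as marginal and conditional R² by
the standard variance-partition formulation (fixed / fixed+random+residual,
and fixed+random / total). Subsets: "aspen present" (≥0.1% cover), >5%,
>10%.

**Model selection.** Starting from all first-order candidate terms plus the
focal aspen term: (1) drop candidates with Wald p ≥ 0.05 (aspen is never
dropped — it is the quantity under study, not a nuisance term); (2) among
surviving pairs with Pearson |r| > 0.3, keep the individually more
predictive term, operationalized as the lower single-term-model AIC;
(3) test aspen × survivor interactions one at a time, admitting an
interaction only if it lowers AIC *and* is significant, repeating until none
qualifies. If the endpoint were ever worse than the starting model by AIC,
the starting model is returned — selection never accepts a deterioration.

**Perimeter effect.** FPE = (P − I)/(P + I) with P from a 120-m band
(60 m each side of the perimeter line, by exact center-to-line distance, not
pixel dilation) and I from the full in-fire area deeper than 60 m. The
"interior" could also be read as only a 60-m inner ring; both are
implemented (`interior_mode="full" | "ring"`), with `full` the default
because the deep burn is the natural reference population. A type absent
from both samples has undefined FPE (NaN). The per-type sign test is the
exact two-sided binomial at null probability ½ under the minimum-likelihood
two-sided convention (two-sided conventions differ; this one is pinned and
cross-checked against integer-arithmetic enumeration in the tests), with
zero and undefined FPE values excluded as ties, and significance at the
Bonferroni threshold α/11. The FPE→abundance inversion
100·((1+FPE)/(1−FPE) − 1) expresses an FPE as the percent by which
perimeter abundance exceeds interior abundance.

**FPE ~ weather and season.** Simple per-covariate linear models on fire
means (≥10 fires; near-constant responses or covariates are rejected or
skipped — a regression on a numerically constant vector produces absurd
p-values), and a penalized B-spline smooth of FPE on day-of-year (basis
dimension 10, penalty weight by generalized cross-validation, ≥20 fires
spanning ≥60 days). The smooth's intercept is carried as a separate
unpenalized constant so the significance test sees only the seasonal
deviation; a smooth penalized entirely away is reported as p = 1.

## The synthetic landscape-fire generator

The generator produces the statistical structure the analysis assumes so
every stage is testable offline.

- **Landscape**: a Gaussian random field smoothed at a correlation length
  ("patchiness", meters), rank-transformed and split at class-weight
  quantiles — marginal class frequencies match the weights to within one
  cell, and patchiness 0 gives independent cells.
- **Spread**: per day, every unburned cell with a burned 8-neighbor ignites
  with probability `base · m(cover) · exp(c·(w_t − w̄))`, clipped to [0,1].
  A day consists of `substeps_per_day` ignition generations (default 1),
  all stamped with that day, so daily progression bands can be several
  pixels wide, as they are for real fires at 30-m grain. Nonflammable cells
  (multiplier 0) are absorbing barriers.
- **Detections**: per day, newly burned cells are thinned at `rate` per 100
  cells, displaced by isotropic Gaussian jitter, and floored at one
  detection per active burn day (`min_per_day=1`) — a daily-revisit sensor
  sees a front at least once a day. Without the floor, slow fires have
  detection-free days whose pixels are absorbed into neighboring days'
  nearest-detection regions, producing artificial multi-day mega-patches.
- **Covariates**: daily unit-variance smoothed fields plus a day-level
  N(0, 0.3²) synoptic mean and an optional linear trend; the name of the
  covariate is folded into the random stream. The first configured
  covariate (the fire-weather index) drives the spread process through its
  daily spatial mean.
- **Reproducibility**: all randomness flows through streams keyed by
  (seed, operation, fire), so runs are bit-reproducible and adding fires
  never perturbs existing ones.

### Default study conditions

The shipped `RunConfig` defaults define the package's study conditions:
180×180 cells at 30 m; fires drawn round-robin from three landscape strata
of aspen abundance (0.06, 0.40, 0.62, each jittered ±15%) with the
remainder split across conifer/herbaceous/shrub/woodland classes;
60-m patchiness; base spread probability 0.45 with 6 substeps per day;
aspen multiplier 0.01; weather coupling 0.15; 30-day maximum; detections at
3 per 100 cells per day with 30-m jitter. The strata emulate a regional
sample of fires spanning conifer-dominated to aspen-rich landscapes — the
setting in which aspen's influence on spread is identifiable at all — and
the strong aspen penalty makes the generative contrast unambiguous at this
small grid size. These magnitudes are calibration choices for a desk-scale
synthetic study, not field estimates.

Under these conditions (24 fires, seed 1): interpolated day-of-burning
matches simulator truth within ±1 day for 82% of pixels; binned mean daily
area and linear spread decrease strictly across aspen bins <10% / 10–25% /
>25%; the mixed-model aspen effect is strongly negative for both responses;
and the aspen FPE is positive in every fire with a Bonferroni-significant
sign test, while warm conifer is uniformly negative.

## What the synthetic study does and does not show

Passing tests establish that the pipeline recovers a known generative
signal — they say nothing about any real fire regime. The simulator omits,
among other things: physical fire behavior (no fuel moisture, slope or wind
vectors, no crown/surface distinction), sub-daily timing and overpass
geometry, sensor footprints and confidence grades, perimeter mapping error,
suppression, roads and terrain controls on perimeter placement, and
real landscape pattern (vegetation classes here are a thresholded random
field). FPE magnitudes in the synthetic study are close to 1 because the
strong penalty keeps aspen nearly unburned; real contrasts are far weaker.
Conclusions about real fires require the real detection/perimeter/vegetation
stack, for which this package supplies the same interfaces (ASCII-grid
rasters, GeoJSON perimeters, CSV detections).

## Numerical and degenerate-input conventions

- Distances are exact Euclidean between cell centers; no chamfer or raster
  approximations.
- DOB nodata is −1; class nodata is −1; nodata cells are excluded from
  proportions, and an all-nodata sample is an error rather than a silent 0.
- Fires too small to have any interior deeper than 60 m are excluded from
  the perimeter analysis and listed in the run manifest.
- `fpe(0, 0)` is NaN (undefined), distinct from 0 (equal representation);
  both are excluded from sign tests but only the former counts as
  undefined.
- The tie rule in DOB interpolation (earlier day wins) uses a 1e-9 m
  tolerance on distance comparisons.
- Problem sizes in the test suite (grid sizes, fire counts, replicate
  counts) are chosen so the whole suite runs in about a minute on one CPU
  while keeping every statistical check at sensible power; the full-size
  calibration checks (e.g., 100-replicate interval coverage) are in the
  acceptance tests.
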