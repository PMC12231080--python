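# fireprogress

Landscape fire-progression analysis for testing whether a low-flammability
broadleaf forest type — quaking aspen (*Populus tremuloides*) — slows
wildfire spread and stops fires at its edges, relative to conifer forest.
The package is aimed at fire ecologists and spatial ecoinformaticians who
work with satellite active-fire detections, burn perimeters, and categorical
vegetation rasters, and it ships with a cellular-automaton landscape-fire
simulator so the entire pipeline runs and is tested at desk scale, without
any satellite or vegetation archives.

## What it computes

**Day-of-burning (DOB) interpolation.** Given a fire's final perimeter and
dated detections, every in-perimeter 30-m pixel is assigned the day of its
nearest detection (planar Euclidean distance, ties to the earlier day).

**Daily spread metrics.** The DOB raster is decomposed into spatially
discrete daily patches (8-connected components of same-day pixels). Each
patch carries

- *daily area burned* `A = n_pixels · (30 m)² / 10⁴` in hectares, and
- *maximum daily linear spread* (m): the largest pixel distance from the
  boundary shared with the previous days' burn; for discontinuous (spot
  fire) patches, from the day's earliest in-patch detection.

**Vegetation effects on spread.** Gaussian linear mixed-effects models

  log₁₀(metric)ᵢⱼ = β₀ + β₁·aspenᵢⱼ + bⱼ + εᵢⱼ,  bⱼ ~ N(0, σ²_fire)

with patch *i* in fire *j*, fit to all aspen-present patches and to >5% /
>10% aspen subsets; analogous contrast models for each other cover type;
and top-down covariate selection (drop non-significant terms, prune
Pearson |r| > 0.3 pairs keeping the lower single-term AIC, then test
aspen × covariate interactions by AIC).

**Fire Perimeter Effect (FPE).** For each cover type, with proportion *P*
in a 120-m band straddling the final perimeter and *I* in the deep burn
interior,

  FPE = (P − I) / (P + I) ∈ [−1, 1].

Positive values mean the type is over-represented where the fire stopped.
Per type, the per-fire FPE signs are tested with an exact two-sided
binomial sign test at a Bonferroni-adjusted threshold (α = 0.05/11 ≈
0.0045), plus FPE ~ weather linear models and a penalized FPE ~ day-of-year
smooth.

**Synthetic landscape fires.** A stochastic contact process on a categorical
landscape: each day an unburned cell with a burned 8-neighbor ignites with
probability `base · m(cover) · exp(c·(w_t − w̄))`, where the aspen
multiplier m < 1 encodes the generative truth the pipeline must recover.
Detections are thinned, jittered samples of newly burned cells; weather
covariates are smooth Gaussian random fields.

## Worked example

The `analysis/` scripts run the full study on 24 synthetic fires (seed 1)
drawn from conifer-dominated, mixed, and aspen-rich landscape strata:

```bash
python analysis/01_simulate_fires.py
python analysis/02_interpolate_dob.py
python analysis/03_spread_metrics.py
python analysis/04_perimeter_effect.py
python analysis/05_spread_models.py
python analysis/06_fpe_models.py
```

which prints, among other things:

```
interpolated 24 fires; fraction of pixels within +/-1 day of truth: mean 0.824, range 0.537-0.948
6257 daily patches from 24 fires
mean daily spread by aspen-cover bin:
       area_ha       max_linear_spread_m
          mean count                mean count
<10%      9.23  3400              190.64  3400
10-25%    5.00  1077              173.31  1077
>25%      0.76  1780               38.26  1780
...
aspen FPE across 23 fires: median 0.999 (23 positive, 0 negative)
log10_area_ha: aspen effect -1.863 (se 0.013, p 0), R2 marginal 0.816 / conditional 0.816, n = 4834 patches / 24 fires
```

Reading this: daily area burned and maximum linear spread both fall
monotonically across aspen-cover bins; the mixed model attributes a strongly
negative aspen effect to both responses; and aspen is over-represented at
fire perimeters in every fire (a significant barrier effect by the sign
test), while warm conifer shows the opposite (interior-concentrated)
pattern. Summary tables land in `results/`; per-fire rasters go to
`scratch/run/` and can be regenerated from the seed at any time.

The same pipeline is available as a console tool
(`fireprogress simulate|interpolate|run-all|make-fixture`), with YAML
configuration.

## Layout

- `src/fireprogress/` — the library: `synthetic` (landscape/fire/detection
  generators), `landcover` (legend reclassification, prior burns, cover
  proportions), `dob` (interpolation, inclusion filters), `metrics` (daily
  patches and spread), `perimeter` (FPE and sign tests), `covariates`
  (sampling, z-scores, aspect transform), `models` (mixed models, selection,
  FPE models), `pipeline` + `cli` (orchestration).
- `analysis/` — the numbered study drivers.
- `docs/methods.md` — models, assumptions, parameter choices, limitations.
- `tests/` — the pytest suite.
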