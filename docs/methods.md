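# Methods

`isodrift` implements a complete desk-scale version of an integrated
insect-geolocation workflow: a sulfur-isotope (δ³⁴S) isoscape with
per-pixel uncertainty, a known-origin calibration from foliage to moth
tissue, continuous-surface Bayesian assignment of natal origin,
biologically constrained wind-trajectory simulation, and the sequential
integration of those layers into ranked candidate source regions. This
note documents the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic data do and do not show.

## The synthetic landscape

Real foliar δ³⁴S in coastal–boreal settings is dominated by marine
sulfate deposition: very high values in a narrow coastal band, a sharp
decline over the first few kilometres inland, a plateau between roughly
10 and 100 km, and a gradual decline extending hundreds of kilometres
further, modulated by mineral-dust deposition at continental scale. The
generator reproduces exactly this structure on a geographic grid with a
sinusoidal coastline (sea to the west):

```
δ³⁴S(cell) = plateau + A / (1 + exp((d − d₀)/w))          coastal logistic
           − s · max(0, d − 100 km)                        inland decline
           − k · (dust − mean dust)                        dust modulation
           + ε,   ε ~ N(0, noise_sd_foliar)                micro-variation
```

with `d` the distance to the coast (km). Defaults — plateau 8‰,
amplitude A = 10.6‰, logistic midpoint d₀ = 5 km, width w = 2 km, inland
slope s = 0.055‰/km, dust coefficient k = 0.8‰ — were fixed once so that
the noiseless field spans ≈ [−8.5, 18.6]‰ and its histogram is bimodal
(coastal band vs inland mass), matching the qualitative
partial-dependence shapes of such gradients. Six covariate layers
(distance to coast, sea-salt deposition, dust deposition, potential
evapotranspiration, wind speed, aridity index) are deterministic
functions of distance-to-coast and latitude, so the noiseless field is an
exact function of the covariates — the property the isoscape-skill tests
rely on. Five of the six are monotone transforms of distance-to-coast by
construction; variable selection therefore legitimately retains only one
or two of them plus the dust layer, and the tests assert probe exclusion
rather than a particular survivor.

Distance to coast is the Euclidean distance transform (in km, cells kept
approximately square by scaling the longitudinal cell size with
cos(latitude)), shifted so land cells that touch the sea sit at 0.

Sampling emulates the field campaigns: foliar sites are drawn without
replacement, stratified over distance bands (0–10, 10–100, 100–300,
>300 km) so both coastal and inland extremes are represented, with
analytical noise of SD 0.16‰ (the mean difference between measurement
duplicates). Known-origin moths are generated per site from the foliar
truth through an affine transfer — default (−0.08, 0.94) — plus
Normal(0, 0.59‰) intra-site scatter, the reported average intra-site
moth SD. These two noise scales, the 23-site × 3–5-moth design, and the
flight-envelope constants below are treated as the study conditions; they
are not tuned per test.

All randomness flows from one integer seed through a named child-stream
scheme (CRC-32 of the stage name mixed into a `SeedSequence`), so any
stage can be regenerated independently and every generator is
bit-reproducible under a fixed seed.

Known emulation gaps: micro-variation is i.i.d. per cell (no spatial
autocorrelation of residuals), covariates carry no noise of their own,
and there are no geological δ³⁴S anomalies. Passing tests therefore
demonstrate correct recovery of the generating process, not skill on
real landscapes with correlated residuals or unmodelled drivers.

## Quantile-forest isoscape

The isoscape is a random-forest regression of site δ³⁴S on covariate
values extracted at the containing cell (no bilinear interpolation,
matching raster-based training-data extraction). Defaults: 1000 trees
(300 in the scaled-down pipeline contexts, see below); predictors-per-split
and minimum leaf size (grid {1..p} × {3, 5}) tuned by 5-fold CV RMSE;
reported skill from seeded 10-fold × 5-repeat CV, with R² the squared
Pearson correlation of pooled out-of-fold predictions and RMSE in ‰.

Per-pixel uncertainty follows the quantile-regression-forest convention:
for a query point, pool the training responses of the leaf each tree
routes the point to (each occurrence counted once per tree) and read
empirical quantiles off the pooled distribution with type-7
interpolation. The uncertainty raster is

```
σ ≈ q(0.841) − q(0.159)
```

— the **full width** of the 68.27% prediction interval, which for
Gaussian residual noise of SD s is ≈ 2s (1.997s exactly). Both
conventions are supported (`sigma_mode="fullwidth"` default,
`"halfwidth"` divides by two); full width is the default because it is
the printed formula in the tradition this follows, and it is knowingly
conservative — overestimated uncertainty is a recognized property of
quantile-forest pseudo-SDs and shows up in the QA bias statistic (the
coverage curve sits above the 1:1 line).

Predictions are masked wherever any selected covariate falls outside its
training range, so the isoscape never extrapolates; nothing finite is
ever emitted outside the mask.

Variable selection is a two-stage stand-in for importance-based selection
packages: (1) permutation importance averaged over repeated fits, with a
seeded pure-noise probe column as the data-driven threshold — predictors
that do not beat noise are dropped; (2) greedy forward addition in rank
order, keeping an addition only if it lowers 5-fold CV RMSE by more than
1% (relative). Fully specified and deterministic under the seed.

## Calibration

Ordinary least squares of individual moth δ³⁴S on the foliar-isoscape
mean at the site cell (individual moths, not site means, are the
observations, so sites with more moths carry more weight). The moth
isoscape is then the affine rescaling of the foliar isoscape:

```
mean′ = a + b · mean
σ′    = sqrt((b·σ)² + s_resid²)
```

The quadrature combination keeps both the spatial (isoscape) and the
biological/analytical (regression residual) noise sources; it is a
standard error-propagation choice where the reference tooling does not
publish its formula. The affine mean round-trips through the inverse
map; σ′ deliberately does not (variance is added, not transported).

## Assignment

For one tissue value y, the likelihood of each valid pixel is the normal
density N(y; mean′, σ′); normalizing over valid cells gives the posterior
with a flat prior over the mask (assignment conditions on origin within
the mapped species range). σ′ is floored at 0.1‰ — safely below the 0.3‰
analytical precision — to avoid degenerate densities. Likelihoods are
evaluated in log space and shifted before exponentiation, so an
observation far from every pixel still normalizes exactly.

Joint posteriors of individuals assumed to share one origin are cell-wise
products, renormalized (the `mean` rule covers the mixed-origin
alternative). Odds-ratio regions are the smallest top-probability cell
sets reaching cumulative mass odds/(odds+1), with ties at the cut
retained together.

Quality assessment is leave-one-site-out: refit the calibration without
the held-out site, assign each held-out moth, and record (a) the
granularity curve — mean fraction of area occupied by the top-q region;
(b) the bias statistic — mean deviation of P(true origin ∈ top-q region)
from the nominal q; (c) the odds ratio — mean posterior at the true
origin over the mean posterior at M = 100 seeded random valid cells. The
exact granularity/bias definitions inside reference QA tools are not
published; these operational definitions are fixed here.

## Trajectories

A deliberately kinematic Lagrangian model (no turbulent diffusion, no
ensemble spread): explicit Euler at dt = 60 s, wind bilinearly
interpolated in space and linearly in time, moth airspeed of 2.5 m/s
added **collinear with the instantaneous wind** (downwind-boosted
transport; zero wind ⇒ no displacement), positions advanced on the
sphere via a local-tangent-plane step, altitude held at the release
level. Temperature at altitude uses a fixed lapse rate of −6.5 °C/km
from the gridded reference field, since no vertical temperature model is
available. The uniform-wind oracle (endpoint within 0.5% of
(|v|+2.5 m/s)·t over 9 h; dt-halving moves endpoints by <0.1%) justifies
the integrator; in a solid-body vortex Euler drifts radially ~1%/h, so
the rotating-flow arc-length oracle is run over a 2-h window.

Releases follow the field protocol: every defoliated cell × three local
release times (19:00, 21:00, 23:00) × three altitudes (300/600/900 m),
9-h duration. Filters mirror the moth's flight envelope: a trajectory
intersecting the 10-km circle around a trap (vertex test plus linear
segment interpolation, so fast trajectories cannot step over the circle)
is retained unless any vertex strictly *before* the first intersection
was below 15 °C (cold discard) or 250 m (low discard); later violations
do not discard; non-intersecting trajectories are counted separately,
and the four verdicts partition every release.

Wind scenarios are analytic fields (uniform, solid-body rotation, a
channel carrying releases from a source zone over a trap, and the same
channel with an embedded sub-15 °C pocket). The scenario default of
22 °C at the reference level keeps the 300–900 m release levels inside
the 15–20.5 °C envelope after the lapse-rate adjustment; the cold pocket
(10 °C) stays below threshold at every altitude.

## Integration and the consensus score

The sources of evidence are combined multiplicatively. In `strict` mode
(default) the per-cell consensus is posterior × 1[defoliated] × 1[≥1
retained trajectory released there] — the closest computable
formalization of "the layers overlap"; `soft` mode replaces the
indicators with normalized release density and defoliation weight.
Candidate cells aggregate into 4-connected regions ranked by total
score, ties broken by the first cell in row-major order. When no
retained trajectory supports any defoliated cell the report carries an
explicit advisory ("consider earlier times and/or more distant source
areas") rather than failing.

## Problem sizes and scaled-down contexts

The package's own recovery harness (`run_synthetic_event`) uses a
60 × 60 grid at 8 km, 70 foliar sites, 23 known-origin sites, 300 trees
without hyperparameter tuning, three immigrant moths, and one release
date — sizes chosen so a complete event (isoscape fit, prediction, QA,
162 trajectories, integration) runs in a few seconds and a 20-event
recovery study stays lightweight. The acceptance script uses 197 foliar
sites (the reference campaign size) with tuning enabled. Full-size
defaults (120 × 120 at 4 km, 1000 trees) remain the library defaults.

## Known limitations

* Quantile-forest σ is conservative (≈ 2s full width) and inflates
  further where the forest is biased (sharp coastal gradient); the QA
  bias statistic quantifies this.
* The calibration attenuates slightly when fit against a fitted (rather
  than true) isoscape, because the regressor carries prediction error —
  visible as slopes just below the generating 0.94.
* Constant-altitude trajectories and analytic winds cannot reproduce
  mesoscale meteorology; trajectory counts are not comparable to runs
  driven by numerical weather models.
* CV folds are random, not spatially blocked; with spatially correlated
  residuals (absent in the generator) random CV would overstate skill.
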