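# isodrift

Isotope geolocation and wind-trajectory tracing of insect dispersal.

Outbreak-driven insects such as the eastern spruce budworm moth
(*Choristoneura fumiferana*) disperse hundreds of kilometres on nocturnal
winds, and tracing where trapped immigrants came from is a core problem
in forest-pest management. `isodrift` implements the full inference
chain for sulfur-isotope geolocation of such events, for movement
ecologists and pest-surveillance analysts:

1. **Isoscape** — quantile random forest regression of foliar δ³⁴S on
   environmental covariates (sea-salt deposition, distance to coast,
   dust deposition, PET, wind speed, aridity), with per-pixel
   uncertainty σ ≈ q(0.841) − q(0.159) (the 68.27% prediction-interval
   width) and masking outside the training range.
2. **Calibration** — known-origin moths regressed on the foliar isoscape
   (δ³⁴S_moth = a + b·δ³⁴S_foliar) rescale it into a moth-tissue
   isoscape, with σ′ = √((b·σ)² + s²_resid).
3. **Assignment** — per-pixel posterior of natal origin,
   P(cell | y) ∝ N(y; mean′, σ′), normalized over the valid range; joint
   posteriors for co-captured individuals; odds-ratio regions; and a
   leave-one-site-out quality assessment (granularity, bias, odds ratio
   vs random locations).
4. **Trajectories** — a kinematic Lagrangian simulator over gridded
   winds with a 2.5 m/s moth airspeed added downwind, releases from
   defoliated (high-density) cells at 19:00/21:00/23:00 and
   300/600/900 m for 9 h, and biological filters (discard if <15 °C or
   <250 m before first intersection with a 10-km trap circle).
5. **Integration** — posterior × defoliation × retained-trajectory
   overlay into ranked candidate source regions.

A first-class synthetic-data module generates coastal landscapes with
the characteristic δ³⁴S structure (sharp coastal decline, 10–100 km
plateau, gradual inland decline; values spanning ≈ −8.5‰ to 18.6‰),
known-origin samples, and wind scenarios, so the entire chain is
testable without field data. See `docs/methods.md` for the models and
assumptions.

## Worked example

```python
import numpy as np
from isodrift import (LandscapeConfig, make_landscape, sample_foliar,
                      sample_known_origin_moths, IsoscapeConfig,
                      fit_isoscape, predict_isoscape, fit_calibration,
                      calibrate_isoscape, posterior_surface)

covs, true = make_landscape(LandscapeConfig(seed=1))
foliar = sample_foliar(true, covs, n_sites=197, seed=1)
model = fit_isoscape(foliar, covs, IsoscapeConfig(n_trees=300, seed=1))
print(f"CV R2 = {model.cv.r2:.3f}, RMSE = {model.cv.rmse:.2f} permil")

iso = predict_isoscape(model, covs)
moths = sample_known_origin_moths(true, covs, 23, (3, 5), (-0.08, 0.94), seed=1)
cal = fit_calibration(moths, iso)
print(f"d34S_moth = {cal.intercept:+.2f} + {cal.slope:.2f} d34S_foliar "
      f"(n = {cal.n}, R2 = {cal.r2:.2f})")

moth_iso = calibrate_isoscape(iso, cal)
surface = posterior_surface(8.4, moth_iso)     # one immigrant's d34S
r, c = np.unravel_index(np.nanargmax(surface.probs.values), surface.probs.shape)
print(f"posterior mode at cell {(int(r), int(c))}, p = {surface.probs.values[r, c]:.4f}")
```

prints (exact values depend on the seed):

```
CV R2 = 0.942, RMSE = 1.43 permil
d34S_moth = +0.51 + 0.93 d34S_foliar (n = 93, R2 = 0.96)
posterior mode at cell (73, 27), p = 0.0003
```

The CV skill says the forest explains ~94% of the spatial δ³⁴S variance
with errors under 2‰; the calibration recovers a near-1:1 foliar→moth
transfer (the generator used slope 0.94); and the posterior mode is the
single most probable natal-origin pixel for a moth measuring 8.4‰ —
low absolute p because mass is spread over thousands of candidate cells.

A complete immigration event — defoliated source zone, wind channel to a
coastal trap, three immigrant moths, trajectory filtering and evidence
integration — is one call:

```python
from isodrift import run_synthetic_event
r = run_synthetic_event(seed=3, with_qa=True)
print(r.recovered, r.qa.odds_ratio, r.summary["trajectories"])
```

The CLI mirrors the stages
(`isodrift synth|isoscape|calibrate|assign|trajectory|integrate|run`);
`isodrift run --seed 0 --out run/` writes every stage artifact with
seed/digest provenance and `--resume` skips completed stages.

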