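# replom

Analysis toolkit for **real-time single-aggregate protein-aggregation
microscopy** — recordings in which each newly bound fluorophore-labeled
monomer yields one diffraction-limited spot that bleaches rapidly, so
the accumulating localization events simultaneously reconstruct a
growing aggregate below the diffraction limit and timestamp its
growth. It is aimed at researchers studying amyloid spherulite
formation (e.g. of insulin) who want per-aggregate growth kinetics and
activation energies rather than bulk averages.

From a localization event table (frame, x, y, intensity, uncertainty —
the standard SMLM table dialect), the pipeline:

1. **Segments** growing aggregates with an approximate Euclidean
   minimum spanning tree on the 30-nearest-neighbor candidate graph,
   cut at the 95th percentile of edge lengths; clusters under 100
   localizations are discarded. Per frame, memberships are refined
   with a 10-neighbor tree cut at 400 nm and the largest connected
   subgroup is kept.
2. **Estimates area** per frame with a Gaussian mixture (one component
   per 5 points, at least 25), defining the aggregate as the region
   whose fitted density exceeds the average density; areas over time
   form the growth curve A(t).
3. **Fits growth laws.** Growth is reaction-limited (dA/dt constant)
   or diffusion-limited (dA/dt ∝ t), with a phase switch at t₀ and
   sigmoidal saturation from t₁ over ~5τ:

   A_lin (anisotropic):  dA/dt = r₁ (t<t₀); r₂ (t₀≤t<t₁); r₂·σ(t) (t≥t₁)
   A_par (isotropic):    dA/dt = r₁ (t<t₀); ½r₂t (t₀≤t<t₁); ½r₂t·σ(t) (t≥t₁)

   with σ(t) = 1/(1+exp(5(t−τ−t₁)/τ)). Fits run a two-pass χ² scheme
   (unweighted pass sets the measurement σ from its residual SD; a
   weighted pass yields parameters and curvature errors). Morphology
   is classified by which law fits better; rates r₁ (linear core),
   r₂ (branching) or r_x (isotropic) are deconvoluted per aggregate.
4. **Extracts activation energies** by Arrhenius analysis: per
   temperature, the mean ln-rate and its SE; weighted regression of
   mean ln-rate on 1/T; Ea = −slope·R.
5. **Measures calibration metrics**: imaging resolution as the FWHM of
   a pooled-spot 2-D Gaussian fitted by Poisson maximum likelihood,
   and fluorophore bleaching lifetime by survival inversion
   (τ = −1/ln s, with s the fraction of emitter traces spanning ≥2
   frames).

A first-class **synthetic generator** simulates the whole measurement
process — isotropic annulus growth or linear-then-branching growth,
Poisson event counts proportional to newly grown area, localization
jitter, exponential photobleaching, sparse background, per-temperature
rate ensembles, spot stacks and bleaching traces — so every stage is
testable with known ground truth and no microscope. See
`docs/methods.md` for the model details and design choices.

## Worked example

```python
import numpy as np
from replom import (SimulationConfig, simulate_aggregate, segment,
                    classify_morphology, ModelKind)
from replom.synthetic import merge_tables, simulate_background
from replom.area_growth import build_growth_curve

cfg = SimulationConfig(morphology="isotropic", r1=0.003, r2=0.00008,
                       t0=300, t1=1400, tau=300, n_frames=100,
                       label_density=20, seed=5)
table, truth = simulate_aggregate(cfg)
field = merge_tables([table,
                      simulate_background((-15000, -15000, 15000, 15000),
                                          100, 300, seed=1)])
clusters = segment(field)
curve = build_growth_curve(clusters[0], field, frame_stride=8, seed=0)
morph, fits = classify_morphology(curve)
sel = fits[ModelKind.A_PAR]
print(f"{len(clusters)} aggregate(s); largest has {len(clusters[0])} localizations")
print(f"growth curve: {len(curve)} frames, "
      f"area {curve.areas[0]:.1f} -> {curve.areas[-1]:.1f} um^2")
print(f"morphology: {morph.value} (true: {truth.morphology.value})")
print(f"fitted parabolic rate coefficient r2 = {sel.params.r2:.2e} "
      f"+/- {sel.param_errors['r2']:.1e} um^2/s^2 (true 8.0e-05)")
```

prints

```
1 aggregate(s); largest has 1567 localizations
growth curve: 10 frames, area 4.0 -> 52.1 um^2
morphology: isotropic (true: isotropic)
fitted parabolic rate coefficient r2 = 7.09e-05 +/- 9.7e-07 um^2/s^2 (true 8.0e-05)
```

The simulated isotropic spherulite is found as one cluster, its growth
curve tracks the generating model, the morphology classifier picks the
parabolic law, and the fitted diffusion-limited rate coefficient lands
within ~11% of the generating value (the residual bias comes from the
mixture-model area scale, not the kinetics fit).

## Command line

Each stage is a subcommand of the `replom` console script:

```sh
replom simulate --out locs.csv --morphology anisotropic --seed 1
replom segment locs.csv --out seg
replom growth locs.csv --out curves.csv --frame-interval 20
replom fit curves.csv --out fits.json --model auto --temperature 45
replom arrhenius rates.csv --out arrhenius.json
replom lifetime locs.csv --link-radius 200
replom render locs.csv --out map.tif --pixel 20 --radius 100
replom run locs1.csv locs2.csv --out rundir --temperature 32 --temperature 45
```

`replom run` drives the full pipeline from a YAML config and writes a
run directory with cluster tables, growth curves, fits, a rates table,
Arrhenius results and a reproducibility manifest.

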