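# Methods

This package analyzes real-time single-aggregate protein-aggregation
recordings made by binding/photobleaching localization microscopy: each
newly bound labeled monomer produces one diffraction-limited spot that
bleaches quickly, so the accumulated localization events both
reconstruct the aggregate below the diffraction limit and timestamp its
growth. The pipeline segments growing aggregates from the pooled event
table, converts per-frame memberships into an area-vs-time curve, fits
piecewise growth laws, classifies isotropic vs anisotropic spherulite
morphologies, and pools per-aggregate rates across incubation
temperatures into Arrhenius activation energies. A synthetic generator
reproduces the measurement process with known ground truth so every
stage is testable without microscope data.

## Segmentation

An approximate Euclidean minimum spanning tree is built on the
symmetrized 30-nearest-neighbor candidate graph of all localizations
(an edge is a candidate if either endpoint proposes it). If the
candidate graph is disconnected, components are bridged through their
mutually nearest point pair, so a single spanning tree always exists
and the subsequent percentile cut is globally well defined. All edges
longer than the 95th percentile of edge lengths (linear-interpolation
percentile, strict `>` removal) are deleted; surviving connected
components with at least 100 localizations are the aggregates,
re-indexed deterministically by descending size then first member
index.

The percentile cut is *relative*: it always removes the longest 5% of
edges. In a field of view that contains sparse background localizations
(false positives, transiently bound monomers) those 5% live among the
long background edges and the dense aggregates survive intact; in a
synthetic field containing only a single uniform-density aggregate the
cut necessarily fragments it. The synthetic generator therefore
provides `simulate_background` so that composed test fields have the
density contrast the method was designed for; single-aggregate studies
can instead skip segmentation and build the cluster directly.

Per frame, the aggregate's *cumulative* localizations (events are
permanent records of growth) are refined with a smaller tree (10
neighbors) cut at a hard 400 nm threshold; the largest connected
subgroup — ties broken by earliest first-detection frame, then lowest
index — is the aggregate for that frame.

## Area estimation

The area of a frame's retained point set is estimated from a Gaussian
mixture with one component per 5 points, at least 25 and at most n/2
components (the upper clamp keeps the fit identifiable at small n;
frames with fewer than 50 points are recorded as gaps because the
25-component floor is ill-posed there). The mixture is fitted by EM
with deterministic k-means++ initialization from the seed and full
covariances.

Two numerical choices matter and were calibrated on a fixture with a
known answer (500 points uniform in a 1000 nm-radius disk, true area
pi um^2):

* **Covariance floor.** Components are regularized with
  `reg_covar = (0.7 x median 3rd-nearest-neighbor distance)^2`.
  Without a floor, components collapse onto small point clumps and the
  fitted density becomes a field of spikes; the 3rd-NN distance (not
  the 1st) is used because repeat detections of one emitter — bleaching
  takes more than one frame — sit at jitter distance from each other
  and would drag a 1st-NN floor far below the true sampling scale.
* **Threshold.** The aggregate is the region whose fitted density lies
  above the *average* density, with the average taken over the
  evaluation grid (the bounding box padded by 3x the largest mixture
  SD, 20 nm pixels). Averaging the density at the member points
  instead is not usable: points concentrate where the fitted density
  is high, so for a near-uniform aggregate the resulting super-level
  set covers only about half the support regardless of smoothing
  (measured 0.47 pi on the disk fixture, vs 0.91–1.00 pi for the grid
  average).

The area is the count of grid pixels at or above threshold times the
pixel area. The estimator is invariant under rigid motions and
equivariant under scaling up to grid quantization. Growth curves keep
the raw per-frame estimates; no smoothing is applied before fitting, so
jumps and fluctuations from mixture fitting and segmentation are
carried into the fit and absorbed by its noise model.

A known limitation: for *sparse branched* structures whose true area is
the summed strip area of thin (200 nm) branches, density smoothing
reports something closer to the branch envelope. Monotone tracking
(rank correlation with truth > 0.95) holds, but the absolute scale can
be off; real branched spherulite coronas are space-filling at the
resolution of the method, where this distortion is much smaller.

## Growth laws and fitting

Radial growth of such aggregates is either reaction-limited (radius
linear in time) or diffusion-limited (radius ~ sqrt(t)); with projected
area A ~ R^2 this gives dA/dt constant or dA/dt ~ t. Both observed
morphologies start in a linear-rate phase (rate r1, um^2/s) and switch
at t0; after the switch the anisotropic morphology grows with a new
constant rate r2 (um^2/s) while the isotropic one grows with
dA/dt = r2 t / 2 (r2 in um^2/s^2). From t1 the growth saturates
sigmoidally with a logistic factor 1/(1 + exp(5 (t - tau - t1)/tau)),
i.e. over a time interval of about 5 tau. The two resulting curve
families are called `A_lin` (anisotropic: linear core then branching)
and `A_par` (isotropic: linear then parabolic).

Curves are fitted by numerically integrating the rate law (composite
trapezoid, 20 sub-steps per observation interval, switch times inserted
exactly into the mesh with one-sided branch evaluation, so the rate
discontinuity of `A_lin` at t0 costs no accuracy; the trapezoid is
exact on constant and linear branches). The chi-square scheme runs
twice: an unweighted pass whose residual SD provides a single uniform
sigma (per-point weighting is available but not the default), then a
weighted pass from which the parameters and curvature-based standard
errors are taken. Bounded trust-region least squares is used with
multi-start over a grid of (t0, t1) quantile pairs (coarse exploration
runs, then one polished run from the best start); bounds keep rates
non-negative, t_first <= t0 <= t1 <= t_last and tau within the
observation span. Noiseless synthetic curves are recovered to better
than 1% in all five parameters; at 5% multiplicative noise the median
rate error is below 10%.

**Model selection.** Morphology is classified by fitting both families
and comparing the *unweighted residual SD* (equivalently, chi-square on
a common measurement sigma). Each fit's own reduced chi-square is ~1 by
construction — its sigma is self-calibrated from its own residuals — so
it cannot rank models. Ties within 1% go to `A_par`, which has fewer
effective shape degrees of freedom. Rates are then deconvoluted:
anisotropic fits yield r1 (linear dendrite core) and r2 (branching
part); isotropic fits yield a single rate r_x, reported as the fitted
r1 of `A_par` — the rate of the initial linear area-growth phase. The
observed isotropic growth is described as linear-then-saturating, and
its single reported rate maps most naturally onto the linear phase;
this convention is recorded in the output metadata rather than asserted
as canonical.

## Arrhenius analysis

Per kinetic phase (linear, branching, isotropic), per-aggregate rates
are grouped by incubation temperature (Celsius in the tables, converted
to kelvin internally); each temperature contributes the mean of
ln(rate) with its standard error. A linear regression of mean ln-rate
on 1/T, weighted by 1/SE^2 (with an automatic unweighted fallback when
any SE is zero, e.g. noiseless input), gives Ea = -slope x R in kJ/mol
with its SE from the regression covariance. Regressing per-temperature
means rather than pooled per-aggregate points matches the conventional
one-point-per-temperature Arrhenius plot with SE bars; a pooled fit is
available as an option. Non-positive rates are excluded with a count.
Ea is invariant under rescaling all rates (only the intercept moves),
and with exactly two temperatures the line is exact with SEs propagated
purely from the inputs. No heat-capacity curvature term is included:
over the narrow 32–45 °C range a straight line describes the data.

## PSF and lifetime metrics

**Resolution.** Single-emitter patches are aligned on their
photon-weighted centroids (patch median subtracted first so flat
background does not bias the centroid) and pooled; a single isotropic
2-D Gaussian plus flat background is fitted to the pooled per-pixel
counts by Poisson maximum likelihood on the pixel coordinates, which
avoids rebinning bias. The per-pixel expectation integrates the
Gaussian over the pixel (error-function differences) rather than
sampling its center. Resolution is FWHM = 2 sqrt(2 ln 2) sigma with SE
from the observed information. A stack whose flat-model likelihood
matches the peaked model is rejected rather than quantified.

**Lifetime.** Detections in consecutive frames within a link radius are
greedily joined into emitter traces. With on-times starting at a frame
boundary and 1-frame sampling, an exponential on-time of mean tau
frames spans >= 2 frames with probability s = exp(-1/tau); the
estimator inverts the observed multi-frame fraction, tau = -1/ln(s),
with the SE propagated from the binomial SE of s. Only a
continuous-time model can produce the observed sub-frame mean
lifetimes from frame-sampled data, which motivates this convention; it
is validated by self-consistent recovery on simulated traces (n = 1885
emitters recovered within 3 SE over 100 seeds). Degenerate cases are
flagged: no multi-frame traces yields an upper bound, all multi-frame
traces an undefined estimate. Dense fields inflate the linked lifetime
(distinct emitters binding near each other in consecutive frames get
chained); the estimator is intended for sparse calibration fields.

## Synthetic data generator

The generator emulates the measurement process, not the photophysics:

* The ground-truth area curve is the numerical integral of the chosen
  growth law starting from a 200 nm-diameter core (the size of the
  initially formed condensates).
* Per frame, the number of new binding events is Poisson with mean
  `label_density x (newly grown area)`; frame 0 deposits the
  pre-formed core. Defaults: 20 s frame interval (the cadence used for
  slow spherulite growth), 50 events/um^2 labeling, 28 nm localization
  jitter (66 nm FWHM / 2.355), 0.7845-frame mean bleaching lifetime.
* Isotropic growth places events uniformly in the newly grown annulus
  of the equivalent-area disk. Anisotropic growth places them on a
  bidirectional 200 nm-wide strip through the core (phase 1), then on
  a branching tree whose tips share the growth: branches spawn as a
  Poisson process along newly grown length with rate increasing
  linearly in distance from the core (0.5 per um of growth per um of
  distance), at a uniform angle within +-70 degrees of the parent.
  Total strip length tracks L = A / w, so in the branching phase the
  *summed strip area* follows the model while the spatial envelope is
  sparser than a real space-filling corona (see the area-estimation
  limitation above). Aspect-ratio ground truth: phase-1 anisotropic
  point clouds have PCA aspect > 2, isotropic ones < 1.3.
* Each emitter is detected in `ceil(L)` consecutive frames for an
  exponential on-time L; every detection carries independent Gaussian
  jitter and a Gamma-distributed photon count (mean 500).
* Rate ensembles for Arrhenius calibration draw ln-rates from
  Normal(lnA - Ea/RT, sigma) with sigma = sqrt(ln(1 + CV^2)), so the
  per-temperature mean ln-rate lies exactly on the Arrhenius line and
  the ensemble-to-fit round trip is unbiased by construction.
* Spot stacks integrate an isotropic Gaussian over the pixel grid with
  uniform sub-pixel center offsets, add flat background, and sample
  Poisson counts. Patches must span at least 3x FWHM.

What the generator does *not* model — blinking and duty-cycle
photophysics, camera EM-gain noise, drift, 3-D structure (growth rates
here are projected-area rates; no attempt is made to reconcile them
with radius-based 3-D rates), spatially varying labeling efficiency —
bounds what passing tests demonstrate: they validate the estimators
under the stated measurement model, not the microscope.

## Problem sizes in the test suite

The suite runs synthetic movies of 80–150 frames with 20–30 events/um^2
labeling (final areas 10–70 um^2, 500–3500 localizations), growth
curves of 150–200 points, 100-replicate ensembles for the Arrhenius and
lifetime calibrations and 50 replicates for resolution; these sizes
make every estimator's sampling error small compared with the asserted
tolerances while keeping the full suite in a few minutes.
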