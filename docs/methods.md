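# Methods

`tumorvasc` re-implements, as verifiable software, the combined in-vivo
workflow used to monitor antiangiogenic treatment of subcutaneous tumors:
raster-scan optoacoustic (OA) angiography with vessel morphometry, diffuse
optical spectroscopy (DOS) of hemoglobin oxygenation, hypoxic-fraction
quantification of stained sections, and the longitudinal two-group
statistics that tie them together. Animal data are replaced throughout by
synthetic data with recorded ground truth, so every stage is validated by
parameter recovery rather than by visual plausibility.

## Synthetic data model

**Vascular phantoms.** Vessels are tubes rasterized onto an isotropic
20 um voxel grid from polyline centerlines with per-vessel radius
(diameters 40-140 um). `generate_vessel_tree` grows tortuous branching
trees by a persistent random walk; `parallel_tube_phantom` and the
fixtures in `experiments` place straight tubes at controlled positions for
recovery tests. The true volume fraction is always the exact voxel count.

**Acoustic forward model.** Each absorbing voxel emits a bipolar
(derivative-of-Gaussian) pulse with 1/r spherical spreading; the focused
detector is treated as a virtual point receiver raster-scanned in the
plane z = 0 (20 um steps, 200 MHz sampling). The pulse width is set so
its -20 dB spectral band matches the 1-30 MHz detector response
(peak at 12 MHz); the band-pass itself is a zero-phase Butterworth.
Animal motion is a smooth bounded random walk of per-B-scan vertical
shifts, applied as a rigid depth displacement of the object. Noise is
additive Gaussian. No acoustic attenuation, dispersion or speckle is
modeled, and the full-wave problem is reduced to delayed point sources:
passing tests therefore demonstrate correctness of the reconstruction and
quantification chain, not robustness to every artifact of real tissue.

**Desk scale.** The default grid is 64x64 B-scans x 384-512 time samples
(~1.3 x 1.3 x 1.5 mm at 20 um steps), chosen so a complete simulate ->
reconstruct -> quantify cycle takes seconds; the field-of-view is a
parameter, so the full 10 x 10 mm geometry is available where needed.

**Cohorts.** Tumor volumes grow exponentially with multiplicative
lognormal noise (CV 0.35). The control rate ln(20)/28 per day reproduces
a 20-fold median increase over the 28-day observation window; the treated
group's rate is multiplied by (1 - 1.513) from a one-week effect-onset
latency, sizing the endpoint separation to ~30-fold. StO2 follows fixed
per-group trajectories -- control declining 0.65 -> 0.46, treated with a
transient rise peaking at day 23 -- with 0.05 absolute noise; total
hemoglobin trends mildly apart with 10% noise; HbO2/HHb derive from the
noisy StO2 and tHb. All generators take explicit seeds and return their
ground truth.

**Hypoxia sections.** Marker-positive and necrotic areas are connected
blobs (thresholded smooth Gaussian fields) covering an exact pixel count,
so the true hypoxic fraction is known to quantization; intensities are
two Gaussian classes plus background.

## OA reconstruction

A-scans are band-passed (7-100 MHz nominal; at 200 MHz sampling this
clamps to a 7 MHz high-pass, with a warning) and migrated per B-scan by
Stolt-type frequency-wavenumber mapping under one-way travel times:
FFT over (x, t), linear resampling of the temporal spectrum at
omega = c*sqrt(kx^2 + kz^2) with Jacobian weight c*kz/|k|, inverse FFT.
Both axes are zero-padded to suppress periodic wrap. Depth sampling is
c/fs (~7.5 um); the operator is linear and focuses an in-plane point
source to within one 20 um voxel. A second pass applies the same operator
in the orthogonal (Y-Z) planes, followed by the Hilbert envelope along
depth.

**Motion correction.** Adjacent reconstructed B-scans are aligned in
depth by cross-correlating their lateral-sum profiles with parabolic
sub-sample refinement; shifts accumulate against the first plane (the
global constant is unobservable). Featureless planes inherit the previous
shift. On depth-stationary scenes the RMS residual against injected
motion is ~0.2 voxel.

**Sound-speed autofocus.** Scalar image-sharpness functionals
(normalized variance, gradient energy, peak amplitude) proved either
insensitive or systematically biased at millimeter scale, because a small
speed error rescales the migration geometry almost uniformly. The
estimator used instead is split-aperture phase detection: the B-scan
block is reconstructed once per lateral half-aperture, and the lateral
misalignment between the two envelope images falls linearly through zero
at the correct speed. The estimator's small constant offset is removed by
self-calibration -- a point source is simulated through the identical
code path at a known speed and the measured crossing offset subtracted.
On scenes dominated by compact or thin (<= 40 um) targets the recovery
error is within ~2 m/s over 1495-1515 m/s; thick-tube scenes degrade to
several m/s as the tubes' own lateral extent enters the correlation, and
scenes whose half-aperture views differ in content (extended oblique
structure) carry no usable focus signal at millimeter aperture -- these
are detected from the error-signal diagnostics and answered with a warned
fallback to the center of the search range rather than a spurious
estimate. The curve returned alongside the estimate is the signed error
signal, not a unimodal sharpness curve.

**Fluence check.** Surface fluence = pulse energy / beam area
(0.3 mJ over a 5.5 mm beam gives 1.26 mJ/cm^2), compared against the
20 mJ/cm^2 ANSI limit for 532 nm.

## Vessel quantification

The chain is 3D CLAHE -> multiscale Hessian vesselness -> series-wide
threshold -> binarization and cleanup -> morphometry.

* **CLAHE** operates on tiles of fixed physical size (default 640 um,
  much larger than any vessel) with the clip limit expressed in uniform
  bin heights (default 2). For longitudinal series the intensity
  normalization range is fixed once (from the reference dataset): a
  per-dataset min-max stretch would silently re-scale every dataset and
  defeat threshold reuse.
* **Vesselness** is the Frangi tube-likeness of sigma^2-normalized
  Hessian eigenvalues, computed per scale and maximized over scales.
  The structureness cutoff gamma is shared across scales and across a
  series (skimage's per-call auto-gamma breaks both comparabilities,
  which is why the filter is implemented here on top of skimage's Hessian
  primitives). The scale-to-size mapping is sigma = d/(2*sqrt(2)): for a
  solid cylinder of radius R the normalized second-derivative response
  peaks at sigma = R/sqrt(2), so this choice makes the per-scale argmax
  land on the true diameter (verified to +/- one 20 um scale step for
  40-140 um tubes). Anisotropic voxels are resampled to an isotropic
  grid first.
* **Thresholding.** `auto_threshold` is the classical 256-bin Otsu of
  the reference response. For series quantification,
  `reference_threshold` defaults to a three-class multi-Otsu binarized at
  the upper cut: the middle class captures the partial-volume shell that
  the system PSF smears around every vessel, and the plain two-class
  split -- dominated by the background class -- lands inside that shell
  and dilates vessels by roughly +60% in volume. Whichever rule is used,
  the value is computed once on a single highly vascularized reference
  and reused (logged) for every dataset in the series.
* **PSF-halo calibration.** Even the best fixed threshold leaves a
  near-constant halo around tubes. The quantification experiments
  therefore image a calibration phantom of known caliber and
  representative density through the identical chain, measure the
  apparent minus true radius, and debias masks by sub-voxel erosion
  (Euclidean distance transform) with that radius -- instrument
  calibration in the usual sense, using no ground truth of the data under
  analysis.
* **Morphometry.** Volumetric vessel fraction is the voxel percentage in
  an axis-aligned VOI (default centered on the intensity centroid);
  skeletons come from 3D thinning with length summed over 26-adjacent
  centerline pairs, branch points as skeleton voxels with >= 3 neighbors,
  segments as components after branch removal; projected vessel area
  thresholds the depth MIP and reports total and per-component mean
  (8-connectivity, minimum particle size optional).

**Accuracy limits.** With 20 um voxels, a 1-30 MHz band and a ~1.3 mm
aperture, tubes of 80-140 um are only 4-7 voxels wide and the lateral
PSF grows visibly with depth. Recovery of volumetric vessel fraction to
within ~20% relative is achievable for single-diameter scenes in a
constant-depth band after halo calibration; scenes mixing diameters and
depths, or packing vessels within ~2 diameters of each other, show
density-dependent biases of up to ~30% from coherent inter-vessel
interference that no global threshold removes. The recovery experiment
is designed inside the regime the instrument can support (120 um tubes,
two close depth rows, >= 220 um spacing) and the limits are stated here
precisely because the tests do not probe beyond them.

## DOS forward model and inversion

Absorption is the hemoglobin two-chromophore mixture,
mu_a = ln(10)*(c_HbO2*eps_HbO2 + c_HHb*eps_HHb) (uM concentrations,
extinctions in 1/(cm*M), output in 1/mm); reduced scattering is the power
law a*(lambda/560)^-b. The bundled extinction table is a synthetic
landmark interpolation (monotone cubic through the textbook Q-band
landmarks: HbO2 peaks 542/577 nm, HHb peak 555 nm, isosbestic crossings
at 529/545/570/584 nm); users can substitute a measured table, and both
the forward and inverse models read the same table, so recovery results
do not depend on the substitution. Water and lipid absorption are
neglected in the 520-590 nm band where hemoglobin dominates.

Reflectance uses the steady-state extrapolated-boundary dipole solution
for a semi-infinite homogeneous medium (internal reflection parameter
from the standard refractive-index polynomial, n_rel = 1.4), evaluated at
the probe's 1.75 and 3.5 mm source-detector separations. The closed form
satisfies the mu_eff log-slope asymptote and similarity scaling to
machine precision.

A single multiplicative gain shared by both distances models the unknown
calibration. Features for inversion are gain-invariant by construction:
mean-centered log-spectra per distance plus the inter-distance log-ratio.
Two solvers recover (StO2, tHb, a, b):

* `lsq_invert` -- bounded multi-start nonlinear least squares on
  log-reflectance (the oracle); noiseless round-trips recover StO2 to
  ~1e-5 and the gain itself to ~1e-3.
* `train_inverse_model` -- a feed-forward regressor (two hidden layers of
  64, Adam, early stopping) trained on 20 000 simulated spectra drawn
  uniformly over StO2 in [0,1], tHb in [10,120] uM, a in [0.5,2.5] 1/mm,
  b in [0.5,2], gain in [0.5,2], with 1% multiplicative noise. Held-out
  noiseless RMSE is ~0.01 StO2 and ~2% tHb; agreement with the oracle is
  within 0.05 StO2 on >= 95% of random in-range spectra.

Replicate probe placements (3-6 per tumor) are inverted individually and
the recovered parameters averaged, which measurably lowers the error
against a single placement.

## Hypoxic fraction

The intensity threshold is a high percentile (default 99.5) of pooled
tissue pixels from control sections stained without the marker; RHF is
the percentage of above-threshold area within viable tissue, necrosis
excluded (a total-section denominator is available behind a flag).
Recovery is within 1 point for separated intensity classes and within 3
points when class SDs reach 0.15 (2 sigma from the midpoint threshold;
larger overlap necessarily leaks misclassified area into the estimate).

## Statistics

Tumor volume V = a*b^2/2 from caliper axes (axes swapped if passed in
reverse order). Optical endpoints are normalized per animal to baseline.
The analysis plan routes tumor volume to nonparametric tests and all
other endpoints to t-tests: exact Wilcoxon signed-rank (full enumeration
of 2^n sign assignments, n <= 12) within groups, exact Mann-Whitney
(enumeration over rank subsets, n+m <= 20, average ranks under ties)
between groups, paired and Welch t-tests, Pearson correlation, and
summary tables (mean, SD, SEM, median, linear-interpolation quartiles).
All tests are two-sided; large samples fall back to the standard
continuity-corrected approximations; no multiple-testing correction is
applied, matching the per-timepoint testing convention. Microvessel
density is count / (fields x field area).

Type-I calibration holds each test inside [0.035, 0.065] at nominal 0.05
(2000 null replicates; the signed-rank calibration uses n = 8 pairs since
at n = 6 the exact test's largest attainable level is 1/32 by
discreteness). The end-to-end study signature -- volume separation
significant from mid-study onward, transient StO2 elevation significant
at day 23 only, significant within-group control growth with the minimal
attainable exact p = 1/32 -- is asserted over a majority of 11 replicate
cohorts, because any single n = 6 draw trips a ~5% per-day false-positive
rate.

## Reproducibility

Every stochastic step takes an explicit seed; `pipeline.run_study`
executes the full chain from one serializable config and reproduces
byte-identical CSVs per (config, seed), stamping each output row with the
config hash. `scripts/acceptance.py` regenerates all headline quantities
from scratch at desk scale in a few minutes on one CPU.
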