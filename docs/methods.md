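# Methods

## Scope and model overview

`lodosim` turns a count-domain CT sinogram acquired at tube current–time
product mAs₀ into a simulated acquisition at any lower mAs, and provides the
apparatus to validate that transformation end to end on synthetic data: a
digital phantom, a 2D parallel-beam forward model, filtered back projection,
and the comparison statistics. The acquisition physics is deliberately
desk-scale — the target of validation is the *noise statistics* of the
simulation, not scanner geometry, so a 2D parallel-beam model with a
monoenergetic effective beam stands in for a helical cone-beam system.
Scatter, beam hardening, bowtie filtration, focal-spot blur and tube-current
modulation are out of scope.

## Acquisition model

A ray with attenuation line integral p (unitless) detects

    counts = Poisson(N₀ · mAs · e⁻ᵖ) + e

where N₀ is the calibration constant (incident counts per bin per mAs,
default 2 000 counts/mAs, i.e. 2×10⁵ counts unattenuated at the 100 mAs
source — a realistic relative noise level for a body protocol) and e is
additive, signal-independent electronic noise. Electronic noise on real
energy-integrating detectors is non-Gaussian, so it is represented by a
*pool of samples* resampled with replacement rather than a parametric
distribution. The default synthetic pool is the mixture
0.9·N(0, s) + 0.1·(Exp(2s) − 2s), rescaled to mean exactly 0 and standard
deviation exactly σₑ = 15 counts; the mixture is right-skewed
(skewness ≈ 0.5), i.e. deliberately and detectably non-Gaussian. Measured
detector samples can be loaded from CSV or HDF5 instead; the pool must hold
at least 10⁴ samples so that resampling does not impoverish the tails.

The log transform back to line integrals clips counts at ε = 0.1 before the
logarithm, so bins that measured zero or negative counts (possible at very
low flux with electronic noise) map to a large but finite attenuation.

## The dose-reduction operator

For dose fraction a = mAs_target/mAs₀ ∈ (0, 1], per bin:

    Y = a·X + sqrt(a(1−a)·max(X, 0))·g + sqrt(1−a²)·e

with g a standard-normal photonic increment and e drawn from the pool. The
coefficients follow from the law of total variance conditioned on the
*noisy* X: the variance X already carries scales by a², the photonic term
supplies the missing a(1−a)λ₀, and sqrt(1−a²) completes the a²-scaled
electronic variance inside X to exactly σₑ². Hence E[Y] = a·λ₀ and
Var(Y) = a·λ₀ + σₑ² — the moments of a genuine acquisition at the target
dose — with no dependence on the source noise level and no noiseless-input
approximation. At a = 1 both noise coefficients vanish and the input counts
are returned bit-exactly.

Numerical choices:

- **Low-flux branch.** The Gaussian increment is adequate for λ ≳ 20. Below
  a configurable threshold (default X < 20 counts) the photonic part is
  realized by binomial thinning: Y_photonic = Binomial(round(max(X,0)), a)
  − a·(round(max(X,0)) − X). The correction term restores the clipped
  remainder (electronic dips below zero, rounding) scaled by a, so the
  conditional mean is exactly a·X in both branches; the residual variance
  error, a(1−a)·(E[max(X,0)] − λ₀), is a fraction of a percent of the total
  whenever electronic noise dominates the clamping.
- **Clamping.** Negative X contributes zero photonic variance (max(X, 0)).
- **Pool consistency.** The plan's pool must match the acquisition
  calibration's σₑ within 1%, otherwise the electronic bookkeeping above
  would not close; mismatches are rejected.
- **Independence.** Bins are treated independently (no detector crosstalk).

## Phantom and ROIs

The default phantom is a 256×256 grid at 380 mm field of view: an elliptical
body with subcutaneous fat (−100 HU), muscle (50 HU), two lungs (−800 HU), a
fluid-filled gallbladder (0 HU) and a vertebral body (700 HU) on an air
background. HU values are conventional textbook numbers (configurable); the
subject of the original validation study is not reproducible from published
data. HU ↔ μ conversion uses μ_water = 0.0203 mm⁻¹ (≈ 60 keV effective for a
100 kV beam). Pixel centers sit at (i + 0.5)·pixel_size from the grid
origin, row-major.

Each tissue carries ten 50 mm² circular ROIs (disk masks over pixel
centers, partial edge pixels excluded). Because a rasterized 4 mm-radius
disk on a 1.48 mm grid contains 21–25 pixels depending on sub-pixel
placement, the generator selects, per site, the seeded sub-pixel offset
whose mask area is closest to 50 mm², keeping the nominal-area contract
within one pixel area. ROI sites are spread 6–13 mm apart inside each organ
to limit the correlation of neighbouring noise estimates.

## Forward projection and reconstruction

Projection is a Joseph-style interpolating ray driver: bilinear sampling of
the μ-grid at half-pixel steps along each ray, summed and scaled by the step
length. The default detector has 1.5× the matrix in bins and spans the FOV
diagonal (180 angles over 180°). Reconstruction is frequency-domain filtered
back projection: projections zero-padded to the next power of two ≥ twice
the detector length, multiplied by |f| ("ramp") or |f|·Hann ("ramp-hann",
the smooth-kernel stand-in, rolled off to zero at the detector Nyquist),
then linearly interpolated and accumulated with weight π/n_angles. Both
kernels are exactly zero at DC. The same kernel is always applied to the
original and simulated arms, so arm comparisons are unaffected by the
kernel's (unknown, proprietary) clinical counterpart. A noiseless water disk
reconstructs to μ_water within ~0.5% at 256²; the residual ~−1% grid bias at
128² is shared by both arms.

## Validation statistics

ROI noise is the sample (n−1) standard deviation of HU in a 50 mm² ROI; the
ROI mean is the CT value. Percent discrepancy is 100·(sim − orig)/orig.
Paired confidence intervals use Student-t quantiles (tissue-level n is
small). Paired t-tests are classical two-tailed tests on differences;
zero-variance identical pairs return (t = 0, p = 1). Cohen's kappa uses
chance agreement from marginal products (the degenerate all-identical case
returns 1 by convention); the chance-level test on pooled observer counts is
an exact two-sided binomial test against p = 0.5. CTDI scales linearly with
mAs at fixed kV. No multiple-testing correction is applied, matching the
original protocol.

Relative CT-value discrepancies are reported only for tissues with
|reference HU| ≥ 100 (lung, bone, fat): for fluid (~0 HU) and muscle
(50 HU) the desk-scale HU measurement error is comparable to the reference
value, making a percentage meaningless. Absolute paired CIs cover all five
tissues.

## The end-to-end experiment

`run_experiment` builds the phantom, projects it once, then per slice
realization acquires a 100 mAs parent scan, simulates every target dose from
it, acquires independent direct scans at those doses, reconstructs both arms
identically, and measures every ROI. All randomness derives from one seed
via `numpy.random.SeedSequence` spawning, in documented order (phantom,
pool, then per slice: source, series, direct scans per target); a fixed
config is bit-reproducible, and the summary JSON records seed, config hash
and library versions.

One slice pair per dose leaves ~6% standard error on the per-dose mean
noise discrepancy: a 50 mm² ROI contains only ~10 independent noise patches
at the smooth kernel's resolution, so a single ROI's noise estimate carries
~20–30% relative error. The original protocol measured ROIs across many
slices of a reconstructed volume; the experiment emulates that with
independent slice realizations per dose (`n_slices`). The validation-grade
setting n_slices = 10 (10 ROIs × 10 slices per tissue/dose/arm) brings the
per-dose mean's standard error to ~1.7%, comparable to the precision evident
in the reference results; the package default is n_slices = 1 (the minimal
5-dose × 2-arm, 10-reconstruction experiment).

Per-dose paired t-tests pair tissue × slice mean values rather than raw ROI
pairs: the ROIs of one arm at one dose share a single reconstruction, whose
common-mode noise level makes raw ROI differences positively correlated and
the t-test anticonservative (measured ~11% of null tests at p ≤ 0.05);
averaging within (tissue, slice) first yields independent, well-behaved
pairs (measured rejection rate 3–4% under the null).

## What the synthetic data does and does not show

The generator reproduces the *statistical* structure of low-dose CT raw
data — Beer–Lambert signal levels, Poisson photon noise, non-Gaussian
additive electronic noise, and their propagation through log transform and
FBP — under an idealized geometry. Passing tests therefore demonstrate that
the dose-reduction operator injects exactly the right first and second
moments and that this survives to image-domain ROI statistics. They do not
exercise scatter, spectral effects, detector crosstalk, helical sampling or
anatomical texture, and say nothing about observer performance on real
images; the observer analytics operate on the published rating tables, not
on generated images.

## Known limitations

- Two-moment matching: third and higher moments of the simulated counts
  differ slightly from a real acquisition (Gaussian photonic increment,
  recombined electronic terms); measured image-domain residual is ~+2%
  noise at the deepest dose reduction (a = 0.1), well within the
  equivalence bands.
- Electronic gain is signal-independent; any signal-dependent detector
  gain would require a calibrated gain map.
- Single-slice 2D only; slice-thickness averaging is not modeled.
- The ramp×Hann kernel is a stand-in for proprietary clinical kernels;
  absolute noise magnitudes are not transferable across kernels.
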