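# Methods

This note records the models behind `fluorotax`, the parameters that
matter, and the design choices made where the methodology was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

Phytoplankton taxa differ in their pigment complements, which reshapes
the chlorophyll-a fluorescence emission band (630–730 nm, peak near
680 nm under ~470 nm excitation). A low-cost spectrofluorometer sees
only this band, at reduced resolution and poor SNR. The chain therefore
(i) denoises, (ii) removes the amplitude variation caused by culture
growth state, (iii) optionally reduces dimension, and (iv) classifies by
Euclidean-distance rules, which is why step (ii) is decisive.

All spectra live on a uniform 1-nm grid; the band crop keeps the closed
interval [630, 730] nm — 101 samples. Population (divide-by-n) variance
is used everywhere a variance appears (SNV moment contract, wavelet
level statistics, covariance matrices), for internal consistency.

## Denoising

**Weighted moving average.** y(λ) = Σ_ρ w(ρ) x(λ−ρ) / Σ_ρ w(ρ) over
ρ = −P..P. Square windows (widths 3/7/11) and Gaussian windows
w(ρ) = exp(−ρ²/2σ²) with σ ∈ {1.04, 1.56, 3.12} samples are the audited
presets; Gaussian windows truncate at P = ⌈3σ⌉ (the tail beyond 3σ is
< 1.2% of the peak weight). Edges use symmetric reflection padding
(no edge-sample repetition): on a 101-point band this avoids biasing the
band edges, where the accessory-pigment slope carries class information.

**Savitzky–Golay.** Least-squares polynomial fit over an odd window,
evaluated at the window centre; polynomial order 2 (orders 2 and 3 give
identical symmetric-window smoothing coefficients, so only the even
order is exposed as a default). Windows 13/17/23 are the audited
presets. Implemented via `scipy.signal.savgol_filter` with `mode=
'mirror'`, the same reflection convention as the WMA.

**Wavelet shrinkage.** Multilevel DWT (PyWavelets) with the Daubechies
wavelet of nine vanishing moments (`db9`), level 6, symmetric boundary
extension. The 101-point band is not dyadic; the boundary-extended
transform is used rather than zero-padding to a power of two because
zero padding injects spurious detail energy exactly at the band edges.
A level is refused when 2^level exceeds the signal length. The noise
scale is estimated once from the finest detail level,
ξ = median(|D₁|)/0.6745 (the MAD→σ conversion for Gaussian noise), and
one universal threshold thr = ξ√(2 ln n) (n = signal length) is applied
to **all** detail levels — soft (shrink by thr) or hard (keep-or-kill,
|d| ≤ thr zeroed). The approximation is never thresholded. ξ is
estimated per measurement, not per culture.

**Smoothing audit.** To quantify distortion, the wavelength×wavelength
covariance matrices (over measurements) of original and smoothed sets
are compared by the RMS difference of their rows at 684 nm (just red of
the Chl-a peak, where inter-wavelength covariance is strongest). Wider
windows distort more; the audit is monotone in window width for square
windows, which the suite asserts as an ordering (the absolute values are
data-specific).

## Normalization

**Min-Max** maps each spectrum affinely onto [a, b] (defaults 0, 1);
extremes land exactly on the endpoints. Simple, but it pins the observed
min/max, flattening the statistics at those wavelengths.

**GSM (growing spectra modeling).** Across a growth series the
fluorescence at every wavelength is linear in the spectrum maximum m:
Fl_λ(m) = a_λ·m + b_λ. The model stores per-wavelength OLS coefficients
fitted on the training split and rescales each measurement by
Fl_λ(target)/Fl_λ(m_measured). At the peak wavelength the slope is ~1
and the intercept ~0 by construction. `target_max` defaults to 1.0 (the
"normalized maximum" is a free unit choice). The fit is global over the
training split, not per culture, because the culture label is unknown at
prediction time. Degenerate denominators (|Fl_λ(m)| < ε) clamp the
factor to 1 and count a warning, keeping pipelines total on flat
baselines.

**SNV.** y(λ) = (x(λ) − μ)·√(σ²_tot/σ²) + μ_tot with the spectrum's own
mean and population variance; defaults (0, 1). The output moments equal
the targets exactly and the map is invariant to affine transformations
of the input.

**Modified SBN.** The wavelet transform decomposes a signal's variance
across scales, so normalization can act per level. Each training
spectrum is decomposed (db9, level 6); the standard deviation of each
retained level's coefficients (and the mean of the approximation) is
regressed on the spectrum maximum, and the regressions are evaluated at
`target_max` to give per-level targets. At prediction time the retained
detail levels (default 3–6; finer levels are treated as noise carriers
and zeroed) are rescaled to their variance targets, and the
approximation to its mean/variance targets; then the signal is
reconstructed. Detail levels are rescaled **without** mean subtraction —
their means are zero up to boundary effects, and preserving the exact
identity "own statistics as targets ⇒ output = input minus the zeroed
fine levels" requires a pure scaling. Detail mean regressions are never
fitted. The unmodified form (unit targets), y = Σ D_i(λ)/√(Σ σ_i²) over
signal-domain detail reconstructions, is provided as
`sbn_unit_normalize`; with an orthonormal boundary (periodization) on
dyadic lengths and all levels retained it reduces exactly to SNV, which
the suite verifies.

## Transformation and dimension reduction

**Derivative.** Forward difference over a band separation of s samples,
y(λ_k) = (x(λ_{k+s}) − x(λ_k))/(s·Δλ), repeated for higher orders; the
output keeps left endpoints and shrinks by s per order. Larger s acts as
a mild low-pass, giving smoother derivative curves — the behaviour the
forward-difference formulation reproduces directly.

**PCA.** Eigendecomposition of the covariance (not correlation) matrix
of the mean-centred data; components sorted by descending eigenvalue,
sign fixed so each component's largest-magnitude loading is positive.
A helper returns the smallest component count whose cumulative variance
reaches a threshold (default 99%).

**Intrinsic dimension (Levina–Bickel MLE).** For each point,
m̂_k(x) = [(1/(k−1)) Σ_{j<k} ln(T_k/T_j)]⁻¹ with T_j the distance to the
j-th neighbour; averaged over points and over k = 6..12 (the estimator
authors' recommended range), rounded to the nearest integer. Duplicate
points (zero distances) are excluded. The estimate is noise-sensitive:
residual measurement noise raises it, so it should be read as an upper
bound on the manifold dimension of denoised data.

**Genetic wavelength selection.** Candidate solutions are n-band subsets
of the grid (default 5 bands, population 100, 20 generations). Fitness
is the mean Cohen kappa of a 1-NN classifier restricted to the
candidate's wavelengths under an internal stratified 3-fold CV (1-NN
because it needs no training, making the fitness cheap). Elitist rank
selection keeps the top 20%; children arise by uniform set-crossover
(duplicates repaired by resampling) and per-gene mutation with
probability 0.1. The search stops at the generation budget or at perfect
fitness; fitness ties break toward the lexicographically smaller
wavelength set, and all randomness flows from one seed, so the elite
trace is reproducible and nondecreasing.

## Classification

All three classifiers use Euclidean distance. **k-NN** (default k = 1)
stores the training set; vote ties break by smaller mean distance, then
by fixed class order. **SOM**: 8×4 grid (32 nodes), weights initialised
at random training samples (box-random initialisation in 51-dimensional
spectral space starts far off the data manifold and handicaps the map),
sequential updates W ← W + α·h_c·(x − W) with a Gaussian neighbourhood
on grid coordinates; α decays linearly 0.5 → 0.01 and the radius
max(rows, cols)/2 → 1 over 200 epochs. **GCS**: grows from a 3-cell
triangle; each signal moves the winner by ε_b = 0.06 and its topological
neighbours by ε_n = 0.002 and increments the winner's counter τ; every
λ_ins = 100 signals a new cell splits the edge between the busiest cell
and its most distant neighbour (connected to both and their common
neighbours, preserving the triangulation; τ_new = (τ_q + τ_f)/2 with the
parents halved, preserving the total). Growth stops at 32 cells — the
same node budget as the SOM — followed by one final adaptation pass; no
cell deletion. Both maps are labelled by majority vote of the training
samples mapped to each unit; unlabelled units inherit the nearest
labelled unit's label (grid distance then weight distance for the SOM,
weight distance for the GCS). Training is bit-for-bit reproducible given
a seed; inference is deterministic.

## Evaluation

Confusion matrices use rows = true class, columns = predicted, in a
caller-fixed class order; fold-averaged matrices carry fractional
entries (multiples of 1/folds when per-fold counts are integers).
Cohen's kappa κ = (p_o − p_e)/(1 − p_e) accepts fractional matrices and
is undefined when chance agreement is 1. Cross-validation is stratified
and seeded; both the kappa of the averaged matrix (the headline number)
and the mean per-fold kappa are reported — on balanced data they differ
only in the third decimal, and the two conventions explain same-size
discrepancies between published summary tables and their printed
matrices.

## Synthetic culture campaign

The real five-culture dataset is not deposited, so the generator
emulates its structure rather than its raw numbers:

* **Shapes.** Each class is a fixed unit-maximum sum of three Gaussians:
  the Chl-a peak (centres 678–684 nm, widths 9–11.5 nm), a red shoulder
  (704–713 nm, relative amplitude 0.20–0.32) and an accessory-pigment
  band (639–651 nm, 0.13–0.28). Gaussians are the simplest shapes
  consistent with measured emission bands; the generator makes no
  radiative-transfer claims. Two classes (the Iso/Amin analogues) are
  deliberately near-identical — their peak-shape separation is about
  half the smallest separation among the other classes — calibrated so
  that the optimal chain still resolves them on degraded data while
  weaker configurations confuse them, reproducing the reported
  discriminability regime of the real campaign (κ ≈ 0.95–0.99 at noise
  variance 0.03 falling to ≈ 0.75–0.8 at 0.2).
* **Campaign structure.** Two samplings per culture: the second covers
  all growth states 1..S, the first only the later states (early
  too-dilute measurements discarded), with independent noise —
  per-class (first, second) counts (16,22), (18,22), (16,22), (10,16),
  (8,22), 172 measurements total. Replicate measurements of the same
  growth state are what makes the nearest-neighbour rule the strongest
  classifier on such campaigns.
* **Growth.** The spectrum maximum follows a logistic curve over
  [1, 10] (arbitrary units); measurement noise is i.i.d. Gaussian with
  σ = 0.05 by default. Fluorescence is therefore exactly linear in the
  spectrum maximum per wavelength (slope = class shape, intercept =
  optional baseline), the structure GSM assumes; at σ = 0 GSM recovers
  the generator shapes to machine precision.
* **Degradation.** Resolution ÷2 (keep every second wavelength — with a
  4-nm optical slit this discards no information), then additive white
  Gaussian noise, default variance 0.03 on the generator's amplitude
  scale. Noise-ladder comparisons reuse one noise seed across variances
  (common random numbers), so the κ trend reflects SNR rather than draw
  luck.

**What passing tests do and do not show.** The generator reproduces the
linear growth structure, the dual-sampling campaign, the class-shape
taxonomy and the confusable pair; it does not model Raman/Rayleigh
scattering (cropped out of the band by design), wavelength-dependent or
signal-dependent (shot) noise, instrument drift between samplings, or
pigment physiology beyond the amplitude-times-shape model. Results on it
validate the chain's mechanics and relative method rankings, not
absolute performance on any real instrument.

## Problem sizes and runtime

The default test suite and the acceptance script run the full campaign
(172 spectra × 101 wavelengths), 5-fold CV, SOM with 200 epochs and GCS
to 32 cells; the GA uses populations of 12–40 and 4–15 generations in
tests (100 × 20 remains the library default). The whole suite completes
in well under a minute on one CPU.

## Known limitations

* The SBN coefficient-variance contract is exact only under an
  orthonormal transform (dyadic length, periodization boundary); on the
  padded 101-point band, reconstruction followed by re-decomposition
  recovers the targets only approximately, a property of redundant
  boundary handling rather than of the normalization.
* Kappa differences between the three classifiers on clean synthetic
  data are within a tie or two; robust orderings emerge only under heavy
  degradation.
* The MLE intrinsic dimension on noisy spectra reads high (noise fills
  all directions locally); it stabilises only after denoising.
* Mixed (multi-taxon) samples are out of scope; the chain assumes pure
  cultures.
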