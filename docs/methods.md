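# Methods

## Scattering transform

The feature extractor is a two-layer wavelet scattering network: cascaded
wavelet convolutions and complex moduli followed by Gaussian averaging at the
invariant scale `2^J`. The modulus demodulates each band-pass channel toward
low frequencies, so the final averaging loses little of the information the
channel carried, while making the output insensitive to translations smaller
than `2^J` pixels and stable to small deformations — the dominant nuisance
variability in B-scans, where the retina's position and tilt vary between
acquisitions but the layer texture carries the diagnosis.

**Filters.** All filters are sampled on the same (H, W) grid as the image and
stored in the frequency domain (origin at index (0,0), negative frequencies
wrapped), so filtering is a pointwise product with the image's FFT. Spatial
kernels are sampled centered at the grid center and circularly shifted so
their phase reference is index (0,0). The Gaussian window uses σ = 0.85 px
and is discretely renormalized to unit sum, so filtering a constant image
returns the constant exactly. The Morlet wavelet is an isotropic Gaussian
window times a plane wave of frequency |ξ| = 3π/4 along the first axis before
rotation, minus the constant `c₂` that cancels its mean. `c₂` is computed
from the sampled grids (ratio of the windowed-plane-wave sum to the Gaussian
sum) rather than from the continuous closed form `exp(−σ²|ξ|²/2) ≈ 0.1346`,
so each discrete filter has a DC response below 1e−10 by construction; at
unit sampling the two differ by about 4e−3.

**Normalization.** The amplitude constant `c₁` is fixed at bank level: all
band-pass filters share one rescaling factor chosen so the Littlewood–Paley
sum `A(ω) = |φ̂_J|² + ½ Σ (|ψ̂_{j,γ}(ω)|² + |ψ̂_{j,γ}(−ω)|²)` has supremum
exactly 1 on the frequency grid. Since `φ̂_J(0) = 1` and every wavelet is
zero-mean, `A(0) = 1` already; the factor is the largest value keeping
`A ≤ 1` elsewhere, which makes the procedure invariant to any prior positive
rescaling of the family. An upper bound of exactly 1 (rather than a tight
frame) makes the transform non-expansive and the energy accounting below
meaningful. The achieved infimum of `A` is recorded on the bank; for the
J=3, r=8 bank on a 128×128 grid it is 0.2716 over frequencies with
|ω| ≤ π/2 (frozen as a regression value).

**Path set.** Second-order paths use strictly increasing scales `j₂ > j₁`:
this matches the coefficient count `r²J(J−1)/2` used in the feature-length
formula, and non-increasing paths carry negligible energy because the modulus
shifts content toward frequencies below `2^{−j₁}`. A flag
(`include_equal_scale`) admits `j₂ = j₁` for sensitivity checks.

**Energy capture.** The claim that orders 0–2 retain more than 98 % of the
energy is made testable as the ratio `E₀₁₂ / (E₀₁₂ + E₃)`, where `E₀₁₂` sums
squared L2 norms of all order-0/1/2 outputs at full resolution and `E₃` sums
the order-3 internal modulus signals over increasing-scale paths. On the
synthetic B-scans (J=3, r=8) the measured mean is ≈ 99.9 %.

**Discretization choices.** Convolutions are circular; images whose sides are
not multiples of `2^J` are reflection-padded up to the next multiple first
and outputs cropped back, since B-scans are non-periodic and wrap-around
would contaminate the coarse scales. Outputs are subsampled on the `2^J` grid
starting at index 0. Internal modulus fields are kept at full resolution —
correct rather than fast, which is affordable at the image sizes used here.
No pre-processing is applied to images (no denoising or contrast
normalization); pixel values are divided by the bit-depth maximum only, and
no log-transform is applied to coefficients by default (an off-by-default
option exists).

**Invariant scale.** By default `J = floor(log2 min(H, W)) − 1`, i.e. the
averaging support `2^J` is half the minimum image dimension rounded down to a
power of two. This is overridable per experiment; the tests mostly use
explicit J.

## Classifier

Each class is modeled as an affine space: the class mean plus the span of the
top-`d` eigenvectors of the class sample covariance (`d = 30` by default;
capped at `n_k − 1` and at the feature dimension). The basis is computed by
SVD of the centered class rows — never by forming the `N_J × N_J` covariance
— with covariance divisor `n_k − 1` and eigenvector signs fixed by making
each column's largest-magnitude entry positive, so fitting is deterministic.
Numerically zero singular directions are dropped, so a class whose training
vectors coincide degenerates gracefully to distance-to-mean. Prediction is
the argmin over classes of the Euclidean distance to the affine space, ties
broken by the first class in sorted label order; negated residuals serve as
scores for AUC. Covariances are per-class (the affine space is defined per
class); no feature standardization or whitening is applied before the PCA.

## Synthetic B-scan generator

The generator renders the morphology a reader uses to tell these classes
apart: a stack of alternating bright/dark horizontal bands with smoothly
jittered boundaries, a global sinusoidal curvature, one optional lesion, and
multiplicative speckle (pixelwise lognormal with unit mean — OCT speckle is
multiplicative). Lesion types: `dome_fluid` (dark disc, placed intraretinally
for DME-like and deep for CSR-like classes), `sub_band_elevation` (dome
pushing the outer bands up, drusen-like), `gap` (full-thickness vertical
notch, macular-hole-like) and `band_thickening`. Default parameters (7 bands
of 5–8 px at 128-px height, speckle σ = 0.3, curvature 5 px) were chosen to
look like a cartoon of a real B-scan at that resolution.

Per-image seeds derive from a counter-mixed seed sequence, so datasets are
reproducible and images independent. What the generator does **not** emulate:
A-scan physics (depth attenuation, shadowing), vessel shadows, motion
artifacts, device-specific noise spectra, or anatomical variability beyond
band thickness and curvature. Passing the synthetic benchmark therefore shows
the pipeline separates layered-texture classes whose differences resemble
the clinical ones; it does not certify accuracy on any real dataset.

## Evaluation

Hold-out splits are stratified per class (train count = `round(f·n_k)`,
half-up, at least one sample on each side) and deterministic in the seed;
k-fold uses stratified folds, falling back to plain shuffled folds with a
warning when a class has fewer than k members. The multiclass AUC is the
macro (unweighted) mean of one-vs-rest ranking AUCs computed from negated
residual scores with midrank tie handling. Splits are per-image; a
`case_id` manifest column exists for group-aware use but grouping is not
applied by default.

## Problem sizes and verification

The test suite verifies the FFT cascade against a brute-force direct-space
reimplementation (explicit kernel-shift circular convolutions, DFT-matrix
frequency responses) at 32×32, J=2, r=4, agreeing to ~1e−15 relative L2;
classifier residuals are checked against an explicit least-squares solve at
1e−10. The standing benchmark is 5 classes × 40 images at 128×128 with
J=3, r=8, d=10 (held-out accuracy 0.925 at seed 7, ≥ 0.9 asserted); energy
capture uses 20 images at 128×128. These sizes keep the full suite in the
low minutes while exercising every path of the cascade.

## Known limitations

- Rotation-invariant or learned filter variants are out of scope.
- Orders ≥ 3 exist only inside the energy accounting, never as features.
- The affine classifier assumes classes are low-dimensional and roughly
  ellipsoidal in scattering space; heavily multimodal classes would need
  several subspaces or a different classifier.
- Real-dataset results depend on acquisition-specific factors the synthetic
  generator does not model; reproducing published OCT accuracies requires
  downloading the corresponding datasets.
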