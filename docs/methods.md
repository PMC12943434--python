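# Methods

## Detector model

A flat detector at normal incidence is described by the wavelength λ (nm),
sample-to-detector distance L (mm), square pixel size (mm), fractional
beam-center pixel coordinates (row, col) and the array shape. Pixel
coordinates are 0-based with pixel centers at integer positions. The
momentum transfer uses the exact relation

    q = (4π/λ) sin(θ),   2θ = arctan(r/L),

where r is the pixel's radial distance from the beam center in mm. The
small-angle approximation is deliberately avoided: a laboratory camera at
L ≈ 20 mm reaches 2θ > 30°, where tan(2θ) and 2θ differ by several
percent. The azimuth is φ = atan2(Δrow, Δcol) mapped into [0, 2π); the
angular origin is arbitrary because the anisotropy phases are free
parameters.

Azimuthal integration averages (not sums) unmasked pixel intensities over
half-open q bins [lo, hi); bins containing no usable pixel are flagged
empty rather than reported as zero.

**Distance calibration.** A lamellar powder standard (silver behenate,
d(001) = 5.8380 nm, orders at qₙ = 2πn/d; the 3rd order at 3.2288 nm⁻¹)
is exposed, the radial centroid of each reflection is located within ±15%
of the radius predicted by the prior geometry (a straight line through the
window edges is subtracted first, and a peak counts as detected only if
its excess clears five times the local Poisson scale), and L is the
closed-form least-squares solution of rₙ = L·tan(2 arcsin(qₙλ/4π)) over
the detected reflections. Measured q positions are rescaled to a common
reference order before their mean, standard deviation and relative
uncertainty (100·std/mean, %) are reported, so multiple orders and frames
are commensurable. On a simulated standard with ≥10⁴ ring counts and a 5%
mis-set prior the recovered distance is within ~0.2% of truth.

## Synthetic frame generator

The generator is the package's test bed: it produces frames with exactly
the structure the analysis stages assume, nothing more.

Expected intensity at a pixel with coordinates (q, φ):

    B(q) + Σ_rings m · exp(−(q − q_c)²/2σ²) · [A₀ + A₁ sin(2φ+φ₁) + A₂ sin(4φ+φ₂)]

with an isotropic amorphous background B(q) = B₀(1+q)^(−γ), Gaussian
radial ring profiles, the two-harmonic azimuthal law per ring, and a
patient-level multiplier m. Observed counts are per-pixel Poisson draws
from this mean; a noiseless mode returns the mean itself. Ring validity
requires A₀ ≥ A₁ + A₂ so the expected intensity can never go negative.
Per-frame phases are drawn uniformly on [0, 2π) (fibril orientation is
random per exposure); an optional separable anisotropic Gaussian kernel
smears the mean before sampling, emulating a slightly non-circular photon
source. Reproducibility is counter-based: the study seed expands into
per-patient and per-frame `SeedSequence` substreams, so a study is
bit-identical regardless of generation order.

**Study layout.** The default study is 24 cancer + 12 fibroadenoma
patients with 8 frames each (288 frames). Each patient carries one
lognormal amplitude multiplier (median 1, log-sd 0.3) shared by all of
that patient's frames — the simplest mechanism producing the
within-patient correlation that patient-grouped cross-validation exists to
handle. The default detector is the laboratory WAXS camera binned 2×2
(128×128 pixels of 110 µm, λ = 0.154 nm, L = 20 mm, beam center off one
corner so a single quadrant reaches q ≈ 29 nm⁻¹); the full-resolution
256×256 geometry and synchrotron SAXS/WAXS geometries are presets. A
long-camera "collagen" study preset places the 3rd-order collagen ring
(q = 0.3 nm⁻¹) at ~83 px with ~5 px radial width.

**Class presets.** Chosen qualitatively and frozen: both classes share the
water ring (~240–250 counts/px at its center, a realistic 30 s laboratory
exposure) and the collagen ring; cancer additionally has weak triglyceride
(q = 1.5 nm⁻¹) and lipid (14 nm⁻¹) rings and, crucially, much stronger
2φ anisotropy (A₁ = 80 vs 8 counts on the water ring, 180 vs 56 on the
collagen ring). With these settings the water-region measurement-level
AUC falls in the 0.8–0.95 range across seeds — separable but overlapping,
the regime the patient-aggregation step is designed for. The generator
emulates counting statistics, orientation randomness and patient effects;
it does not emulate detector artifacts (dead pixels, flat-field error),
background subtraction residuals, intra-specimen heterogeneity or
multi-class pathology, so green tests here demonstrate correctness of the
analysis machinery, not clinical performance.

## Preprocessing

Region masks keep the union of q intervals intersected with an optional
pixel-aligned rectangle (boundary inclusive); everything else is set to 0
and recorded in a boolean exclusion mask. Masking uses pixel-center q
values, is idempotent, and an empty keep-region is an error. The water
analysis keeps q ≥ 16 nm⁻¹ (above the lipid maximum); the collagen
analysis extracts the annulus |q − 0.3| ≤ 0.03 nm⁻¹ with 72 azimuthal
bins (the default annulus half-width of 10% of q_c and the bin count keep
well over 100 pixels per bin at the long-camera geometry).

**Beam-shape correction.** corrected(p) = I(p) − ½[I(p − s·r̂) + I(p +
s·r̂)] along the ray r̂ from the beam center, s = 5 px, nearest-pixel
lookup by default (bilinear sampling is an option). The radial second
difference annihilates fields affine in radius, so smooth anisotropic
halos vanish while sharp rings survive with a positive scale factor
1 − exp(−s²/2σ_r²) on a Gaussian ring of radial width σ_r. Pixels whose
sample points leave the detector, hit a mask, or lie closer than s to the
beam center (where the inward sample would cross it) are flagged invalid,
never silently filled. The correction is exactly linear in the input.

## Anisotropy fitting and the (A₁, A₂) classifier

The two-harmonic model is linear in the parameterization a·sin(kφ) +
b·cos(kφ), so the fit is plain OLS (SVD solve, equal bin weights, empty
bins excluded) — no initialization or convergence concerns, and on
noiseless data it coincides with iterative nonlinear least squares.
Amplitudes are reported canonically as √(a²+b²) ≥ 0 with phase
atan2(b, a) ∈ [0, 2π); rotating a profile by δ shifts the phases by 2δ
and 4δ while leaving amplitudes unchanged. If the angular coverage cannot
separate the harmonics the design is rank-deficient and the error names
the offending harmonic. Amplitude standard errors come from the
homoscedastic OLS covariance and the delta method; under Poisson noise at
200 counts/bin these SEs match the empirical spread to a few percent.

The (A₁, A₂) route classifies measurements in the two-coefficient plane
with the same grouped out-of-fold protocol as the Fourier route
(standardize → project → class-weighted logistic model) and reports the
Youden operating point with patient-level bootstrap intervals. Whether
the coefficient-plane scatter should be cross-validated at all is a design
choice; this package always uses the grouped protocol to exclude leakage.

## Fourier-magnitude features

2D FFT of the masked frame → complex magnitudes → division by the
zero-frequency magnitude (total brightness) → fftshift → ln(x + ε) with
ε = 10⁻⁶ → row-major flattening, in exactly that order. ε guards the
exact zeros that masking introduces; it is exposed in the API. Masked
pixels enter the transform as zeros, so the mask shapes the spectrum — 
accepted, because one mask is shared by every frame of a study. Full-length
vectors are kept despite the conjugate symmetry of real input; the
redundancy is harmless under the downstream projection. Features are
invariant to circular translation and to positive rescaling of the frame,
and every value is ≤ ln(1+ε) for non-negative input.

## Classification and inference

Folds: StratifiedGroupKFold with the patient id as the group and the frame
label as the stratification variable, k = 5, shuffled with a fixed seed;
every frame of a patient shares one fold, which the code asserts.

Per-fold model: per-feature standardization → PCA → L2 logistic
regression with class weights n/(2·n_class) and C = 1 (configurable), all
fit on training rows only. The PCA uses **whitening** (unit-variance
components): with whitening the pipeline is exactly invariant to feature
duplication or rescaling absorbed by the projection, which plain PCA + L2
logistic is not (duplication rescales the projected coordinates and the
regularized solution shifts). 20 components is the default; metrics are
flat beyond ~10 on the default study, and the count is capped at the
training-fold rank with a warning. A Random Forest variant satisfies the
same fit/score contract for comparison; its internals are scikit-learn's.

Patient scores are arithmetic means of the patient's frame probabilities.
ROC/AUC/AP use scikit-learn (trapezoidal AUC ≡ concordant-pair fraction
with half-credit ties; AP as the step sum over descending ranks). The
Youden threshold maximizes sensitivity + specificity − 1; ties go to the
higher threshold (fewer predicted positives), and an all-tied score table
yields J = 0 with a warning.

Bootstrap: N patients resampled with replacement, B = 2000; single-class
resamples are redrawn and counted; 2.5/97.5 percentile intervals for AUC
and AP; per-resample ROC curves are linearly interpolated onto a fixed
101-point FPR grid (curves anchored at (0,0) and (1,1)) and pointwise
percentiles form the 95% envelope. In a nested simulation at 36 patients
the intervals cover the generating AUC slightly below the nominal 95%
(88–99% band) — the familiar small-N percentile-bootstrap undercoverage.

Permutation test: patient labels shuffled with scores fixed (default
10,000 shuffles), add-one estimator p = (1 + #{null ≥ observed})/(1 + n)
so p is never 0 and never below 1/(n+1). The AUC null is evaluated
through the rank-sum statistic and the AP null through a vectorized step
sum over the fixed descending-score order, making 10⁴ shuffles effectively
instantaneous. p-values are invariant under strictly increasing transforms
of the scores.

**Null calibration.** Shuffling labels at the frame level before training
leaves the measurement AUC near chance (the 288 frames behave as
quasi-independent units once labels are random). Patient-level shuffles
keep only 36 independent units, so null AUCs there scatter with sd ≈ 0.1
— which is why the patient-level null check uses the wider [0.35, 0.65]
band while the frame-level check uses [0.4, 0.6].

## Problem sizes used in tests

The default study (288 frames at 128×128) is sized so a full
simulate→classify pass takes a few seconds; the replicate studies for the
aggregation property (100 seeds) and the permutation-calibration study
(200 tables × 999 shuffles) reuse that scale. The bootstrap coverage
simulation uses B = 300 per study over 200 synthetic 36-patient score
tables — percentile-stable and cheap.

## Known limitations

- Distance-only calibration: detector tilt and rotation are not refined.
- Polarization, solid-angle, flat-field and absorption corrections are
  assumed already applied upstream; frames arrive corrected.
- Labels are binary (cancer / fibroadenoma); the benign-non-fibroadenoma
  class of earlier lipid work is out of scope.
- The beam-shape correction removes smooth radial-affine anisotropy; it
  does not undo ring-width anisotropy from strong smearing (a second-order
  effect it can amplify when the annulus is much wider than the shift).
- The exact pixel boundaries of the published extraction rectangles are
  not reproduced; region specs are configuration, with the 16 nm⁻¹ water
  cutoff as the anchored default.
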