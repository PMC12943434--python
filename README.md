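# xrdtissue

Classification of breast-tissue 2D X-ray diffraction patterns — cancer vs
fibroadenoma — from collagen and water structural signatures, with honest
patient-level statistics.

Lipid-based X-ray scattering markers separate cancerous from benign breast
tissue well, but fibroadenoma (a common benign tumor) mimics the cancer
lipid signal. Two features that do discriminate are (i) the *azimuthal
anisotropy* of the collagen diffraction rings — invasive tumors are
associated with preferentially aligned collagen fibrils — and (ii) the
broad water O–O scattering maximum near q = 20 nm⁻¹, which inherits the
collagen anisotropy through hydration-water structuring. This package
implements both analysis routes over 2D detector frames, plus a synthetic
Debye–Scherrer frame generator with the statistical structure the analysis
assumes (Poisson counting noise, per-frame random fibril orientation,
patient-level random effects, anisotropic beam smear), so the whole
pipeline is testable end to end.

## The models

**Ring anisotropy.** The azimuthal intensity of a diffraction ring is fit
by the two-harmonic model

```
I(φ) = A₀ + A₁ sin(2φ + φ₁) + A₂ sin(4φ + φ₂)
```

by ordinary least squares on the linear basis {1, sin 2φ, cos 2φ, sin 4φ,
cos 4φ}; each measurement is summarized by the non-negative amplitudes
(A₁, A₂), with the random fibril orientation absorbed into the phases.
Beam-shape anisotropy is removed beforehand by a radial second difference:
`I(p) − ½[I(p − s·r̂) + I(p + s·r̂)]` with s = 5 px, which annihilates any
radially affine background.

**Fourier-magnitude features.** Each masked frame (e.g. the water region
q ≥ 16 nm⁻¹) is mapped to `ln(|F(frame)| / |F|₀₀ + ε)`, centered and
flattened — translation-invariant, exposure-invariant features in which
directional order shows up without explicit alignment.

**Patient-grouped evaluation.** Frames of one patient are correlated, so
cross-validation is grouped by patient (StratifiedGroupKFold, 5 folds);
each per-fold model is standardization → whitened PCA (20 components) →
class-weighted L2 logistic regression. Out-of-fold probabilities are
averaged per patient; ROC AUC, average precision and the Youden operating
point are reported at both levels, with patient-level bootstrap 95%
intervals (2000 resamples) and a patient-level permutation test (10,000
label shuffles, add-one p-value).

The detector model uses the exact relation q = (4π/λ)·sin(θ) with
2θ = arctan(r/L) (no small-angle approximation), and the
sample-to-detector distance is calibrated from silver behenate
(d = 5.8380 nm; 3rd order at q = 3.2288 nm⁻¹).

## Worked example

```sh
python analysis/04_water_classification.py
python analysis/05_inference.py
```

prints (seed 1):

```
measurement AUC 0.897 (288 frames), patient AUC 0.934 (36 patients)
Youden point: sensitivity 0.88, specificity 1.00 at threshold 0.814
patient AUC 0.934 (95% CI 0.84-1.00), AP 0.974 (95% CI 0.93-1.00)
permutation p-values: AUC 0.0001, AP 0.0001 (10000 shuffles)
```

That is: on a simulated 24-cancer/12-fibroadenoma study, classifying the
water region alone separates individual frames with AUC 0.90, improves to
0.93 once frame probabilities are averaged per patient, and the
permutation test puts that far outside chance. The other numbered scripts
under `analysis/` cover study simulation (01), distance calibration (02)
and the collagen (A₁, A₂) route (03); all write their tables to
`results/`. The same stages are scriptable via the `xrdtissue` command
(`simulate`, `calibrate`, `mask`, `correct`, `fit-anisotropy`, `features`,
`classify`, `report`, `run`) or a single YAML config through
`xrdtissue run`.

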