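# Methods

This note documents the computational choices behind `dermafuse`: what each
stage computes, the defaults and why, what the synthetic cohort does and
does not emulate, and the known limitations.

## Diffuse-reflectance indices

All indices operate on the effective optical density OD_λ = −log₁₀ R_λ of a
reflectance spectrum sampled by linear interpolation at landmark
wavelengths (spectrometer grids rarely hit the landmarks exactly; at ~1 nm
pitch linear interpolation is unbiased in practice).

* Melanin index `M = 100·(OD₆₂₀ − OD₇₀₀)`.
* Erythema index with the Dawson grouping,
  `E = 100·[OD₅₆₀ + 1.5·(OD₅₄₅ + OD₅₇₅) − 2·(OD₅₁₀ + OD₆₁₀)]`. The
  coefficient sum is zero, so E of a flat spectrum is exactly 0 — the
  property that fixes the bracketing.
* Hemoglobin content `H = (OD₅₄₅ − OD₅₂₉)/16 − (OD₅₇₀ − OD₅₄₅)/25`,
  a two-band estimator around the oxyhemoglobin absorption features.
* `Linearity` is the ordinary-least-squares slope of **reflectance** (not
  OD) against wavelength restricted to 650–800 nm; `Error_linearity` is the
  RMS of the fit residuals (dimensionless, reflectance units). The RMS
  definition was chosen as the natural scalar "deviation from the linear
  approximation"; alternatives (max residual, SE of the slope) would order
  lesions similarly.
* Malignancy coefficient
  `Rt = (R_h(500)·R_n(700)) / (R_h(700)·R_n(500))`, computed against the
  **pointwise mean** healthy spectrum because lesion and healthy
  acquisitions are not paired. Identical spectra give Rt = 1 and
  Rt(a,b)·Rt(b,a) = 1.

Per-lesion coefficients M/E/H/Linearity/Error_linearity are normalized by
the mean of the same coefficient over the volunteer's healthy spectra
(individual skin-tone removal); Rt is already a lesion/healthy contrast and
is not re-normalized. A healthy mean of exactly zero raises a named error
rather than silently clipping — E and H can legitimately be near zero on
pale skin, and the caller should know.

## OCT texture

The chain is: background threshold → threshold filter → denoise → features,
with Shannon entropy taken from the **raw** scan before any filtering.

* The background threshold is mean + population σ of a noise-only region
  below the tissue.
* The threshold filter zeroes pixels with intensity ≤ threshold (the ≤ is
  deliberate: the filter is idempotent on already-zeroed scans).
* Denoising is a 3×3 grayscale erosion ("window width of 3 pixels" read as
  a square structuring element) followed by a 2-D Gaussian with σ = 1.5 px
  truncated at 4σ, rounded back to 8-bit.
* First-order statistics use population moments of the nonzero ROI pixels;
  kurtosis is **non-excess** (normal = 3), matching classical texture
  practice. A zero-variance ROI reports skewness/kurtosis 0 with a warning.
* Co-occurrence matrices use the full 8-bit range (256 levels) by default —
  the scans are 8-bit and down-quantization discards contrast — with an
  optional `levels` override. A pixel pair contributes only when **both**
  members are nonzero, extending the background-exclusion rule to pairs.
  Matrices are symmetrized (count matrix + transpose) before normalization,
  the standard Haralick construction which also makes opposite directions
  redundant. Offsets: 0° = +d columns, 45° = up-right, 90° = up,
  135° = up-left, with rows increasing downward.
* Haralick features: energy Σp², contrast Σ(i−j)²p, correlation
  Σ(i−μᵢ)(j−μⱼ)p/(σᵢσⱼ) (defined as 1 when a marginal variance vanishes —
  a constant ROI is perfectly self-correlated), entropy −Σp·log₂p, and
  homogeneity Σp/(1+(i−j)²) (inverse difference moment; the 1/(1+|i−j|)
  variant is a config option). Entropies are in bits; the base only
  rescales.

The 65-element vector is ordered: 4 FOS, Shannon entropy, then
feature-major `⟨feature⟩_a⟨angle⟩_d⟨distance⟩` over 5 × 4 × 3 names.

## Ultrasound shape

The consensus ROI is the pixelwise AND of the two annotator masks, reduced
to its largest 8-connected component. Descriptors are computed in mm using
the pixel spacing (per-axis for anisotropic grids):

* Perimeter is the literal boundary-chain length: Moore-neighbor tracing of
  the outer boundary, summing Euclidean step lengths (1 or √2 pixels scaled
  per axis). This overestimates smooth contours by a few percent — a known
  property of pixel-chain perimeters that cancels in comparisons between
  lesions measured the same way.
* The ellipse descriptors come from the ellipse with the same normalized
  second central moments as the region (including the spacing²/12
  per-pixel variance term), eccentricity = focal distance / major axis,
  orientation counterclockwise-positive from the image horizontal in
  (−90°, 90°].
* FilledArea, MaxFeretDiameter/Angle and Solidity follow standard
  region-property semantics (hole-filled area; maximum boundary caliper;
  area over convex-hull area, computed as a pixel-count ratio so it never
  exceeds 1). The prose glosses of these names in terms of a "rectangle"
  conflict with the standard vocabulary the names come from;
  bounding-box-based variants were deliberately not guessed as defaults.
* Tortuosity is literally Perimeter/Area (1/mm); it is scale-dependent by
  construction.

Regions smaller than 5 pixels are rejected as unmeasurable.

## Fusion, scaling, weighting

The three channels are acquired at different sites on the lesion, so
modality rows within a tumor are paired by independently permuting each
modality's rows with a seeded generator and zipping — each source row is
used at most once, the observation count per tumor is the minimum over
modalities, and the pairing is reproducible from the logged seed.

Min–max scaling is fit on the **training fold only** and applied to the
held-out tumor (values may fall outside [0, 1]; no clipping; constant
features map to 0). A `scaling="global"` flag reproduces the simpler
pre-scaling variant, which leaks fold information and exists for
comparison only. Class weights are inverse-frequency,
`w(c) = N/(K·count(c))`, normalized so the observation-weighted mean is 1
and the loss magnitude stays comparable across folds.

## Classifier and evaluation

The learner is a gradient-boosted decision-tree multiclass model (xgboost,
softmax multiclass objective; its two-class special case is the logistic
objective) with per-observation class weights. Defaults: depth 4, learning
rate 0.1, at most 500 rounds, early stopping after 50 non-improving rounds
on a stratified 20 % slice of the training fold. The reference
implementation of this design tuned its hyperparameters by hand and did not
report them, so these defaults are deliberately conservative shallow-tree
settings and all are exposed in `ClassifierConfig`. Note the early-stopping
slice is stratified by class, not grouped by tumor — it mirrors the
original overfitting-detector design, and with few tumors per class a
grouped slice is often impossible; the consequence is that early stopping
rarely fires on within-tumor-correlated data, so the round cap is the
effective regularizer.

Cross-validation is grouped leave-one-tumor-out: one fold per tumor, all of
that tumor's observations test-only, scaling and weights re-learned per
fold. A fold that loses a class entirely proceeds with the remaining
classes and logs a warning; its held-out probabilities for the missing
class are 0.

The confusion matrix is built from the argmax of the out-of-fold
probability vectors. Per class: Sens = tp/(tp+Σfn), Spec = Σtn/(Σtn+Σfp),
Prec = tp/(tp+Σfp), F1 the harmonic mean, IoU = tp/(tp+Σfn+Σfp); macro
values are unweighted class means reported with across-class standard
deviations. Zero-denominator ratios are reported as 0 and flagged so macro
means stay computable on degenerate folds. Threshold curves sweep a fixed
0–1 grid (step 0.01, configurable) one-vs-rest; ROC points are
(FPR, 1−FNR) on the same grid. Feature importance is total split gain of
the final model (trained on all observations); per-observation attributions
are exact TreeSHAP values whose sum plus the base value reproduces the
model margin to numerical precision.

## Synthetic cohort

The generator is phenomenological, not biophysical: the pipeline consumes
landmark optical densities, slopes, texture statistics and mask geometry,
so the generator plants exactly those.

* **Spectra** (450–950 nm, 1 nm): flat baseline OD 0.30 plus a melanin ramp
  (constant below 620 nm, linear to zero at 700 nm — so M responds as
  100·melanin_slope), Gaussian hemoglobin dips at 545/575 nm (σ = 12 nm,
  driving E and H), a linear reflectance tilt beyond 650 nm (driving
  Linearity), and additive Gaussian reflectance noise (sd 0.004 ≈ 1 % of
  signal). Healthy-skin spectra use fixed mild baseline values
  (melanin 0.05, dips 0.05, tilt −10⁻⁴) regardless of class.
* **B-scans** (150×72 px at 5.34/7.32 µm pitch): unit-variance Gaussian
  random field with the class correlation length (Gaussian-filtered white
  noise), scaled by the class contrast, shifted to the class mean
  intensity; a |N(6, 2.5)| background strip below the tissue feeds the
  threshold estimator. The fixed ROI (104×60 px = 555×439 µm) satisfies the
  ≥ 534×400 µm rule. The correlation length maps monotonically (inversely)
  onto d = 1 contrast, giving a testable ordering.
* **Masks** (192×192 px at 0.06 mm): an ellipse with the class major-axis
  diameter and eccentricity, boundary radius modulated by smooth periodic
  roughness (harmonics 2–6, clipped to ×[0.4, 1.45] so large rough lesions
  stay star-shaped and in the field of view); each annotator adds small
  independent boundary jitter, so the pair overlaps without coinciding.

Variability has three levels: per-class parameters, per-tumor biological
jitter (lognormal, sd 0.05), and per-acquisition jitter of the imaging
knobs (lognormal, sd 0.10) modelling probe repositioning between repeated
scans of the same lesion. The acquisition level matters: without it each
tumor collapses to a point in OCT/US feature space, boosted trees memorize
those points, and any held-out tumor falls outside every learned region —
within-tumor spread must cover between-tumor variation for grouped
cross-validation to be learnable from few tumors per class.

Two presets are provided. `"well-separated"` encodes strong class contrasts
that respect the ordinal relations observed clinically (melanin highest for
benign and pigmented lesions; erythema/hemoglobin highest for the nodular
and lowest for the superficial form; circularity high for benign, low for
superficial). `"overlapping"` keeps 30 % of each parameter's deviation from
the across-class mean and doubles all noise scales — same ordering, much
weaker separation. The default cohort composition is 37 tumors
(2/2/15/3/5/10 per class) with 10 observations each.

What passing tests on this cohort show: the extractors compute their
definitions correctly, the fusion and cross-validation are leakage-free,
and the classifier recovers planted class structure when it exists (and
degrades when it does not). What they do not show: performance on real
tissue. The generator has no OCT speckle physics, no acoustic shadowing,
no chromophore unmixing, no spatial correlation between modalities of the
same tumor, and its class distributions are unimodal by construction.

## Problem sizes and numerical notes

The evaluation tests run the full default cohort (370 observations,
37 folds) over 5 seeds and both presets — chosen as the smallest design
that exercises every class count of the study composition; a single run
takes about a minute on one core. GLCM accumulation is vectorized
(`bincount` over level pairs) and matches a double-loop pair enumerator
exactly. Degenerate cases are defined, not special-cased at call sites:
correlation of a zero-variance GLCM is 1, skewness/kurtosis of a constant
ROI are 0 (flagged), empty-class metric ratios are 0 (flagged), an empty
annotator intersection raises. All randomness flows through
`numpy.random.Generator` seeds; repeated runs are bit-identical on the
same platform, including the on-disk cohorts.

## Known limitations

* Boundary-chain perimeters biased a few percent high on smooth shapes
  (affects Circularity and Tortuosity absolutely, not comparatively).
* The moment-ellipse axes assume a filled, roughly convex region; very
  concave consensus ROIs make MajorAxisLength exceed the Feret diameter's
  0.95 bound only in pathological cases excluded by the generator.
* With two tumors per class, grouped LOOCV trains on a single tumor of
  that class; per-class sensitivities are then highly variable (visible as
  the large across-class standard deviations in the reports).
* The early-stopping slice shares tumors with the training rows, so the
  overfitting detector is weak under within-tumor correlation (see above).
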