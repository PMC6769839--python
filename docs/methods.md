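# Methods

`hsimargin` implements a complete analysis chain for delineating squamous
cell carcinoma (SCC) at the resection margin of excised head-and-neck tissue
specimens from gross-level hyperspectral images (HSI). Because no patient
data are distributed with the package, every stage is exercised and validated
on synthetic tissue phantoms whose construction is described below; what the
phantom results do and do not establish is stated explicitly at the end.

## Imaging model and calibration

A specimen is imaged as a hypercube `H x W x C`: two spatial axes at
25 µm/pixel and `C` spectral bands. Reflectance cubes span 450–900 nm in
5 nm steps (`C = 91`); autofluorescence (and dye-fluorescence) cubes span
500–720 nm in 10 nm steps (`C = 23`). Raw sensor counts are flat-fielded
band by band against a dark-current frame `D` (closed shutter) and a white
reference `W`:

    R = (raw − D) / (W − D)

`(W − D)` is the sensor's usable dynamic range, which is why it is the
default denominator; instruments whose white normalization was not
dark-subtracted are covered by the `denominator="white"` switch. Reflectance
above 1 arises at specular glare pixels and is deliberately **not** clipped:
glare stays in the analysis, and clipping exists only as a visualization
option. Elements with a non-positive denominator are flagged and zeroed
rather than silently becoming NaN.

RGB composites are convex per-channel combinations of bands under Gaussian
kernels (defaults 650/550/450 nm, σ = 30 nm — canonical R/G/B centers inside
the 450–900 nm grid; the σ→0 limit degenerates to single-band selection).

Because flattened specimens thin out toward their free edge, the outer
10 pixels (0.25 mm) of the tissue mask are eroded away before any training
or evaluation. The erosion uses a square (Chebyshev) structuring element of
radius `n`, so "n pixels at the edge" is exact along axes and diagonals and
erosions compose additively (`erode(erode(m,a),b) = erode(m,a+b)`).

## Margin-distance evaluation

The registered tumor–normal interface on a margin (TN) specimen carries
roughly 1–2 mm of combined registration/penetration-depth uncertainty, so a
single global score would be dominated by pixels whose true class is
genuinely ambiguous. Performance is therefore reported as a function of
distance from the margin: the interface is the set of tissue pixels with a
4-neighbor of the opposite class, distance is the Euclidean transform of
that set scaled to millimeters (40 px = 1 mm at 25 µm/px), and "TN at
d mm" removes all tissue pixels strictly closer than `d` — on **both**
sides of the interface — before computing metrics. `d = 0` (the "actual"
margin) uses every trimmed tissue pixel. Masks are nested in `d`; a
specimen whose geometry cannot supply a given `d` (no pixels, or a single
class, beyond it) is marked unattainable at that `d` and dropped from that
distance's aggregate. The opposite reading — evaluating only pixels within
`d` — is available as `semantics="include_within"` for sensitivity analysis.

## Intra-patient protocol (personalized ensemble LDA)

This arm emulates building a model for one patient in the operating room:
train on that patient's primary-tumor (T) and all-normal (N) specimens, test
on the same patient's margin (TN) specimen. Features are raw calibrated
pixel spectra (no derivative or PCA transform). Pixels are split into 5
stratified folds; 500 linear discriminant learners are distributed evenly
over the folds and each is fit on a bootstrap bag (63% of the training
folds' rows). A learner is the two-class Gaussian discriminant

    w = Σ̂⁻¹ (μ₁ − μ₀),   Σ̂ = (1 − γ) S + γ diag(S)

with pooled within-class covariance `S` (denominator n − 2), empirical
priors in the intercept, and logistic posterior. The diagonal shrinkage
(default γ = 0.1) guards near-singular covariances when a small specimen
supplies few pixels relative to the 91 bands. The ensemble score is the
mean posterior over learners; held-out fold scores provide the validation
ROC from which the operating threshold is chosen. Bagging was chosen as the
ensembling scheme because LDA is deterministic — resampling is the standard
way to obtain a diverse ensemble of a fixed-size learner population — and
`bag_fraction = 1` degenerates to a plain LDA refit for testability.

## Inter-patient protocol (patch CNN)

Models intended for unseen patients are evaluated with patient-disjoint
5-fold cross-validation: every scene of a patient lives in exactly one fold,
each fold is the fully-independent test group once, and one of the
remaining folds is held out for early stopping and operating-point
selection, so test labels never touch training or threshold choice.
Training always uses T and N scenes only; testing is on held-out patients'
T/N scenes (tumor-vs-normal experiment), their TN margin scenes (margin
experiment), or both from one training pass.

Scenes are decomposed into 25 × 25 × C patches on a stride-12 lattice
(13-pixel overlap), plus a flush window at each image edge so border tissue
is always covered. Training keeps windows at least half covered by tissue
and labels a patch cancerous when ≥ 50% of its tissue pixels are tumor;
optionally, mixed-purity patches (tumor fraction in a configurable band
such as 0.2–0.8) can be dropped. Inference keeps every window touching
tissue, and per-pixel probability is the exact mean of all overlapping
patch scores (the reconstruction is checked against a brute-force
accumulation oracle, not approximated).

The classifier is a compact inception-style network: a 1×1 "spectral
mixing" stem (default 16 channels) followed by two blocks of parallel
1×1/3×3/5×5 branches (8 channels each, concatenated, ReLU), global average
pooling, and a 2-way softmax. Spatial resolution is preserved throughout,
and the stem accepts any band count (3, 23, or 91). The network is
implemented directly in numpy with explicit backpropagation; the same
machinery supplies the class gradients needed for saliency. Training uses
Adam (lr 10⁻³) with decoupled weight decay (10⁻³) on convolution and dense
weights, per-epoch undersampling of the majority class, at most 50 epochs
(default 30), and early stopping on validation AUC with the best-epoch
parameters restored; validation loss breaks AUC ties so that continued
convergence at a saturated AUC still refreshes the kept weights (without
the tie-break, a phantom the network separates after one epoch would
freeze near-initialization weights, which destroys gradient-based saliency).
Weight decay matters for the same reason: it is the pressure that shrinks
weights on uninformative bands once the classes are separated. This
network is deliberately small enough to train on one CPU at phantom scale;
the protocol, not a specific large architecture, is what the package
commits to, and the topology is configurable.

## Evaluation

AUC of the ROC is the primary metric (threshold-free, robust to class
imbalance); the trapezoidal computation handles ties as simultaneous
threshold crossings and therefore equals Mann–Whitney pair counting
exactly. Hard metrics are computed at an operating point chosen **on
validation data only** by maximizing Youden's J = TPR − FPR (ties broken
toward higher specificity, then the higher threshold; a closest-to-(0,1)
criterion is available). Sensitivity and specificity use the standard
definitions TP/(TP+FN) and TN/(TN+FP); PPV and NPV are reported alongside.
Aggregates report median and mean AUC with SEM per distance. Modality
comparisons use a paired one-tailed t-test on per-patient metrics
(`t = mean(Δ)/(sd(Δ)/√n)`, df = n − 1), with pairs dropped when either side
is missing and degenerate zero-variance differences flagged; no
multiple-testing correction is applied across modality comparisons, and
this is deliberate — consumers should treat the p-values as descriptive.

Specimen-type identification (T/TN/N) is scored by decomposing margin
specimens into tumor and normal components on both the truth and prediction
side: matched components pair directly, and an unmatched component pairs
with the opposite side's component — so a true TN predicted as all T is one
true positive plus one false positive, and a true T predicted as TN is one
true positive plus one false negative.

## Spectral saliency

Per-wavelength importance is extracted from the trained patch classifier
via class-activated gradients. For each correctly classified patch of the
target class, the grad-CAM map (ReLU of channel-weighted last-block
activations, weights = spatially averaged class gradients) gates a per-band
attribution that is summed over space; per-patch profiles are min-max
scaled, averaged, and rescaled to [0, 1]. The band attribution is the
**gradient magnitude** at the input. Gradient×input was evaluated and
rejected as the default: multiplying by raw reflectance systematically
favors bright NIR bands over class-informative ones on phantoms where the
informative bands are known by construction (it remains available as
`reduction="gradient_x_input"`, along with a mean-centered variant).
Profiles from independently trained models (e.g. the five fold models of a
cross-validation run) are averaged: informative bands recur across models
while incidental "reference" bands are training-specific, so the consensus
profile sharpens. Recovery was validated on phantoms whose class contrast
is injected only at the 560/565 nm grid bands: the aggregated SCC profile's
two most salient bands are exactly those.

## Synthetic phantoms

The generator emulates the statistical structure the analysis depends on,
not tissue biophysics. Each patient contributes a T/N/TN triplet on an
elliptical tissue support (default 96 × 96 px ≈ 2.4 mm at 25 µm/px — a
deliberately scaled-down specimen so a full cohort run fits in CPU
minutes). Class spectra are phenomenological: a smooth reflectance baseline
with a broad 545 nm hemoglobin depression; SCC adds deeper oxygenated-
hemoglobin dips at 560/565 nm and *higher* NIR reflectance (normal tissue's
fat/collagen/water absorbs more above 700 nm). The SCC-minus-normal curve
is scaled by `class_separation` (0 ⇒ identical classes) and floored at
±0.04 per band so the classes differ everywhere — sized so that per-patient
mean spectra separate at every band (Welch p < 0.01) in a 10-patient
cohort, with cushion. Fluorescence phantoms reuse the machinery on the
23-band grid with emission peaks instead of dips. Nuisance structure:
per-pixel lognormal intensity variation (σ = 0.05), per-patient lognormal
factors (σ = 0.03), additive sensor noise (σ = 0.01 in reflectance units,
injected in count space so calibration recovers the field to within
3 × σ), smooth lamp spectrum and vignetting in the white frame, and a
configurable fraction of near-saturated glare pixels (reflectance > 1).
TN specimens carry an irregular (Fourier-perturbed) tumor blob; the two
class spectra are *blended* across a ±8 px zone around the interface,
emulating partial-volume/registration ambiguity — this is what makes
margin-distance stratification informative on phantoms (tumor-vs-normal
testing beats margin testing, and AUC rises with exclusion distance).
T specimens include a small (≈5%) normal pocket; N specimens are pure
normal. Scene-level seeds derive deterministically from the master seed
(patient index × scene index), so cohorts reproduce bitwise.

What phantoms do **not** emulate: histology-to-HSI registration error in
the masks (masks are exact by construction), dye chemistry, spatial texture
within a class beyond lognormal pixel noise, anatomical-site heterogeneity,
and realistic specimen sizes. Passing phantom tests therefore demonstrates
that the pipeline's machinery is correct and recovers planted structure;
it does not certify clinical performance, and the package makes no claims
about patient-data accuracy.

## Numerical choices and degenerate inputs

- Calibration flags (rather than NaNs) non-positive denominators; empty
  evaluation masks yield warned, undefined metrics; empty erosion warns.
- Distance transforms use the exact Euclidean transform on the pixel grid,
  scaled by resolution; distances are validated against exhaustive
  pairwise minima on masks up to 32 × 32.
- LDA covariance solves raise a targeted error suggesting shrinkage when
  singular at γ = 0; bootstrap bags are redrawn until both classes are
  present (≤ 50 attempts).
- ROC ties contribute half-credit; the `+inf` threshold sklearn emits for
  the empty-prediction point is clamped to max(score)+1 so operating
  points are always usable cuts.
- CNN initialization is He-scaled and fully seeded; per-fold seeds derive
  from the experiment seed, and identical configuration + seed reproduces
  identical reports (the numpy implementation has no nondeterministic
  backend).
- Default problem sizes (10-patient cohorts, 96 px phantoms, ≤ 30 epochs)
  are the package's chosen demonstration scale; every size is a parameter.

## Known limitations

- The inception-style network is a compact stand-in sized for CPU training;
  its exact topology is configurable but not a port of any specific large
  architecture.
- Saliency recovery is validated only through the phantom-recovery
  property; different attribution reductions disagree on real data and the
  default (gradient magnitude) is a documented choice.
- The intra-patient arm treats pixels as exchangeable across folds within a
  patient; spatial autocorrelation makes pixel-level validation AUC an
  optimistic estimate of within-patient generalization (the TN specimen
  test is the honest readout).
- Margin-distance aggregates mix patients with different attainable
  distance ranges; the per-patient `attainable` flag and pixel counts are
  reported so consumers can see the shrinking sample.
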