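# Methods

This note documents the models and procedures implemented in `wbckit`,
the parameters that matter, the design choices made where the
published description of each technique leaves the design open, and
what the synthetic-data experiments do and do not demonstrate.

## Nucleus segmentation

**Model.** A stained smear is treated as a mixture of three color
populations: pale background, pink erythrocytes, and the purple
nucleic stain shared by leukocyte nuclei and platelets. Each pixel is
a vector v ∈ ℝ³ of RGB intensities. For an ordered, linearly
independent basis {v₁, …, v_k} whose last member is the nucleus stain
color, classical Gram-Schmidt gives orthogonal directions u_j, and the
weight vector w = u_k = v_k − Σ_{j<k} proj_{u_j}(v_k) satisfies
⟨w, v_j⟩ = 0 for j < k and ⟨w, v_k⟩ = ‖u_k‖² > 0: background and
red-cell pixels project to ≈ 0, nucleus pixels project high. The
projection image is min-max normalized and binarized by Otsu's
criterion (exhaustive maximization of between-class variance on a
256-bin histogram), three such masks from three stain-color candidates
are fused by pixelwise AND, and 8-connected components smaller than a
configurable area are removed.

**Basis estimation.** The reference colors are not known a priori, so
they are estimated per image: k-means with three clusters in RGB over
a subsample of at most 10 000 pixels (fixed seed; deterministic). The
cluster whose center maximizes the purpleness score R + B − 2G is the
nucleus population; the other two centers are the shared non-nucleus
references. The three stain-color candidates are the pixels at the
10th, 25th and 50th percentiles of the purpleness score *within* the
nucleus cluster. Using three candidates spanning the dimmer half of
the stain distribution makes the AND fusion robust to stain intensity
and illumination differences: a pixel must respond to all three
projections to survive. An image whose per-channel standard deviation
falls below 1.0 (8-bit units) has no color contrast to cluster and is
rejected (or yields an empty mask in non-strict mode).

**Parameters.** `min_area_frac` defaults to 0.1 % of the image area
(≈ 415 px at 720×576) — platelets are an order of magnitude smaller
than nuclei, so the default separates them comfortably and is exposed
for other magnifications. Small-object removal runs once, *after* the
AND fusion: fusion only shrinks regions, so a single final cleanup
subsumes per-mask cleanups.

## Local features (SIFT)

The detector is the standard scale-space construction: per octave,
levels blurred incrementally to σ_i = σ₀·k^i (σ₀ = 1.6,
k = 2^{1/(L−3)}, L = 5 levels), octaves downsampled by two, adjacent
levels subtracted into DoG stacks; strict 26-neighbor extrema are
keypoint candidates. Gaussian kernels are truncated at 6σ so the
incremental blurs compose to the direct blur within ~1e-9 — the
semigroup identity the construction relies on. By default the pyramid
starts one octave *below* input resolution (2× bilinear upsampling):
this resolves chromatin-scale texture and lets coarse keypoints keep a
descriptor window inside the small single-cell crops the pipeline
feeds it.

Published descriptions of the method leave keypoint screening and
several descriptor details open; the completions here are the
conventional ones, flagged as interpretations:

- contrast threshold |DoG| ≥ 0.03 (images on [0, 1]) and
  principal-curvature ratio ≤ 10, both configurable — without them
  sensor noise floods the detector;
- sub-pixel refinement by a single 3D quadratic fit, offsets clamped
  to half a voxel;
- orientation from a 36-bin, Gaussian-weighted (1.5σ) gradient
  histogram with parabolic peak refinement; one dominant orientation
  per keypoint (no multi-peak duplication, keeping one descriptor per
  detection);
- the 16×16 sample grid is spaced at 0.5σ per step, rotated to the
  keypoint orientation; gradients are sampled bilinearly, accumulated
  trilinearly into 4×4 spatial cells × 8 orientation bins, Gaussian
  weighted with scale equal to half the window; the 128-vector is
  L2-normalized, clamped at 0.2 and renormalized (affine illumination
  robustness). Keypoints whose rotated window leaves the image are
  dropped rather than padded.

Rotation invariance (90° rotation: ≥ 80 % of matched keypoints within
descriptor distance 0.3) and scale invariance (2× upsampling preserves
≥ 50 % of keypoints) are verified in the test suite, and detected
keypoint locations are cross-checked against the independent
scikit-image SIFT implementation.

## Convolutional feature extractor

Architecture: one valid (unpadded) 3×3 convolution with N_k = 16
filters and ReLU, two 2×2/stride-2 max pools, a 128-wide fully
connected ReLU layer (the feature layer), and a softmax output used
only during training. Spatial dimensions shrink by 2 at the
convolution and halve at each pool; a 64×64 crop yields a 3 600-wide
flattened map. Convolution is implemented as cross-correlation — with
learned filters the kernel flip is immaterial. Training is plain
minibatch SGD (lr 0.01, batch 16) on mean cross-entropy with He
initialization; all randomness derives from one seed, so training is
exactly reproducible. Analytic gradients for every parameter tensor
are validated against central finite differences (relative error
≤ 1e-5 required; observed ~1e-8).

Crops are scaled to [0, 1] and centered at zero before entering the
network; without centering, the bright smear background biases every
activation identically and slows early SGD noticeably.

The final classifier is not the softmax: the penultimate activations
are extracted as features and handed to the sparse-representation
classifier below.

## Sparse-representation classification (WTPTSSR)

Training columns and the test vector are unit-L2-normalized. Phase 1
solves X = (AᵀA + t·WᵀW)⁻¹Aᵀy with the locality weight
W = diag(‖y − aᵢ‖ᵏ), penalizing distant training samples; the M
columns with smallest single-column residual conᵢ = ‖y − aᵢxᵢ‖² are
kept (ties to the lowest index). Phase 2 solves the ridge system
X̄ = (ĀᵀĀ + γI)⁻¹Āᵀy on the reduced dictionary; each class is scored
by the residual of reconstructing y from its own selected columns
(classes with no selected column score ‖y‖² = 1), and the arg-min
class wins, ties to the lowest class id. At k = 0 the weights collapse
to the identity and the method is numerically identical to plain
TPTSR, verified to 1e-10 against an independently coded
implementation.

Defaults t = 0.01, γ = 0.01, k = 2, M = min(40, N/2); no canonical
values are published, so all are exposed in the configuration. A
regime worth knowing: when M exceeds the feature dimension m, several
classes can reconstruct y almost exactly and the residual margin
shrinks — smaller M or larger γ restores it. The defaults are kept
moderate for the feature dimensions the pipeline produces (384).

**Feature fusion.** How the descriptor set and the CNN vector combine
is unspecified in the published method and is this package's own
design: the variable-size descriptor set is pooled to a fixed
256-vector by elementwise mean and max (zeros when a cell yields no
keypoints), concatenated with the CNN feature vector. In the pipeline
the two blocks are L2-normalized separately before concatenation so
that neither modality dominates the classifier's column normalization.

## Evaluation metrics

For automatic mask A and manual mask M:

- TS = |A ∩ M| / max(|A|, |M|) × 100. The source formula as typeset
  uses a union in the numerator, which would force TS ≥ 100 for every
  input and contradicts all published values below 100; the
  intersection reading is implemented and the union reading treated as
  a typographical error.
- RDE = ½(rms(d_E) + rms(d_T)) where d_E are Euclidean
  nearest-neighbor distances from each automatic boundary pixel to the
  manual boundary and d_T the reverse; boundaries are 4-connected
  inner boundaries (image edge counts as background). The typeset
  formula is ambiguous about its square roots; the RMS reading — the
  standard form of this criterion — is the default, and
  `rde_variant="mean_square"` provides the literal no-root reading.
- OR = Q_p/(U_p + D_p), UR = U_p/(U_p + D_p), ER = (Q_p + U_p)/D_p
  with Q_p the manual pixels missing from the automatic mask, U_p the
  automatic pixels absent from the manual mask, and D_p the manual
  object size.

All three families are tested against brute-force set-arithmetic and
all-pairs distance oracles on random mask pairs.

## Synthetic data

The generators are pure functions of a specification plus a seed and
are bitwise reproducible.

- **Smears** default to the 720×576 frame of typical smear captures:
  3 nuclei (unions of 1–5 overlapping ellipses, radius 20–32 px,
  purple (130, 60, 160) ± jitter), 40 pale-red RBC disks, 10 purple
  platelet specks of radius 2–4 px, pale background, Gaussian sensor
  noise σ = 3 (8-bit). Objects are placed without overlap by rejection
  sampling (an overcrowded specification raises). The ground-truth
  mask marks exactly the painted nucleus pixels; platelets are
  excluded, which is precisely what makes area-based platelet
  rejection testable. Nucleus and platelet size ranges are disjoint by
  construction. The palette gives the nucleus projection ≳ 3:1
  contrast over background at default noise.
- **Cell crops** caricature the five leukocyte classes through
  (lobe count, eccentricity, chromatin texture frequency/amplitude):
  round smooth lymphocytes, elongated monocytes, bilobed coarse
  eosinophils, densely granular basophils, multilobed neutrophils.
  Texture is band-limited Fourier noise confined to the nucleus.
- **Feature clusters** place five class prototypes at a common
  magnitude with minimum pairwise distance `separation × σ_within`,
  plus isotropic Gaussian noise. Equal-magnitude prototypes mirror the
  nonnegative feature vectors they stand in for (rectified activations
  and pooled descriptors sit well away from the origin), so class
  identity lives in direction — the part that survives the
  classifier's column normalization. Separation 0 produces class-blind
  data on which accuracy must drop to chance.

**What passing tests show — and don't.** Perfect recovery (TS = 100)
on synthetic smears demonstrates that the projection, thresholding,
fusion and cleanup chain is implemented correctly, because flat-
stained, non-touching nuclei are exactly the geometry the model
assumes. Real smears violate those assumptions — stain gradients
within a nucleus, touching or overlapping cells, chromatic camera
noise, out-of-focus regions — so synthetic TS says nothing
quantitative about performance on clinical images. The same applies to
the end-to-end classification accuracy: the synthetic morphology
classes are separated by construction and the reported
cross-validated accuracy (typically ~80 % with 20 crops per class)
characterizes the pipeline on this synthetic family only.

## Problem sizes and numerical choices

The recovery experiments use 20 smears at full 720×576 resolution, 10
cluster seeds with 30 training / 10 test samples per class at m = 10,
and 20 crops per class (64×64) with 20 training epochs for the
end-to-end run — sizes chosen so the whole reproduction script
completes in well under a minute on a single CPU while the statistics
remain stable. Linear systems are solved by LAPACK (`numpy.linalg
.solve`); both ridge phases are verified to satisfy their normal
equations with residual ≤ 1e-8. Degenerate inputs have defined
behavior throughout: constant projections yield empty masks with a
warning, gradient-free keypoint windows yield orientation 0 or are
dropped, zero dictionary columns and single-class training sets raise
with the offending index named.

## Known limitations

- Cytoplasm is not segmented; metrics and crops are nucleus-only.
- One orientation per keypoint; heavily anisotropic neighborhoods with
  two equal gradient modes get only the larger one.
- The CNN is intentionally small and CPU-bound; no augmentation,
  momentum or learning-rate schedules.
- WTPTSSR cost is O(N³) in the number of training columns per test
  sample; the intended regime is the few-hundred-sample dictionaries
  typical of smear studies.
- The synthetic generators do not attempt photorealism (no stain
  diffusion, no cell overlap, no focus blur); conclusions about real
  collections require real annotated images.
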