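# Methods

This note records the models, the synthetic data they are exercised on, the
numerical choices, and the limits of what the desk-scale experiments show.

## The prediction model

A specimen is a *bag* of tiles; only the bag carries a label (multiple
instance learning). The model has four parts.

**Per-slice encoder.** A strided CNN (`conv 3×3, stride 2` blocks, widths
configurable; desk scale 8-16-32) maps one RGB focal-plane slice to a
feature vector. Pooling concatenates the spatial **mean and maximum** of
each final-stage channel before the linear head: the mean carries stain and
occupancy statistics, the maximum carries peak texture responses that
averaging washes out (fine chromatin, granular structure). Slices are
encoded independently, so a `(T, T, 3, Z)` tile becomes a `D×Z` feature
stack and column `z` describes plane `z` exactly.

**Contrastive pretraining.** The encoder (plus a discarded 2-layer
projection head) is trained with the temperature-scaled InfoNCE objective
over pairs of augmented views of each slice; rows `2i, 2i+1` of a batch are
the positive pair, all other rows are negatives, similarities are cosine.
Temperature defaults to 0.5. The full-scale augmentation menu is random
resized crop (area scale 0.4-1.0), rotations {0°, 90°, 180°, 270°},
horizontal flip, color jitter, grayscale, Gaussian blur and solarization;
the desk-scale preset weakens it (crop 0.7-1.0, lighter jitter, no
grayscale/solarize) because at 32 px the strongest views destroy the mutual
information between the two views of a slice and a small encoder's loss
plateaus at the random-similarity floor.

**z-integrator.** Each tile's `D×Z` stack is treated as a multichannel 1D
signal over focal planes: two `conv1d(kernel 3, same padding) + ReLU`
blocks, then a collapse of the z axis. Two additions matter at desk scale:

- *z-decomposition* (default on): the input stack is split into its
  across-z mean and the residual axial profile, stacked as parallel
  channels. This is information-preserving, but it makes cross-slice
  contrasts — the axial signal — linearly accessible instead of entangled
  with slice-shared content. Without it, a signal confined to one plane is
  invisible behind specimen-level appearance variation (probes on identical
  features: held-out AUC ≈ 0.5 entangled vs ≈ 0.85 decomposed+engineered).
- *collapse*: `mean`, `max`, or `select` (one plane, used by attribution
  diagnostics). The desk-scale configurations use **max**: averaging over Z
  planes dilutes a single-plane signal by 1/Z under the rectified noise of
  the other planes, and measured held-out AUC for a plane-localized signal
  was ≈ 0.5 with mean collapse versus ≈ 0.7 with max on the same features.
  Full-scale stacks with stronger encoders may prefer mean; it remains the
  type default.

**Aggregation and head.** Attention pooling scores each tile
representation with `wᵀ tanh(V h)` (hidden width 16 at desk scale) and
softmax-normalizes over the bag; mean and max pooling are selectable
alternatives, and attention with forced uniform weights reproduces mean
pooling identically. A linear layer + softmax gives the two-class
probability. Training is end to end (encoder frozen) with cross-entropy,
Adam, batch size one specimen, minority ids oversampled with replacement to
the majority count each epoch, early stopping on training-loss plateau
(patience 10), optional decoupled weight decay, and optional best-of-k
restart selection by final training loss (guards rare bad initializations
of the small head). Feature stacks are z-scored per dimension with
statistics from the training split only.

## The synthetic z-stack generator

The generator emulates a focal-plane-stacked scan of an H&E section.

**Optics.** Every scene object lives at a depth within the section;
rendering plane `z` blurs each depth layer with a Gaussian of width
`σ(Δz) = σ₀·√(1 + (Δz/a)²)` px (`σ₀ = 0.4`, axial resolution `a = 2 µm`
by default), composites hematoxylin/eosin optical densities, and converts
to RGB by Beer-Lambert (`RGB = 255·exp(−OD)`) with the Ruifrok-Johnston
stain vectors plus mild multiplicative noise. A single-plane configuration
renders everything in focus (a 2D scan has no axial structure). The defaults
mirror the emulated protocol: 256 px tiles at 0.25 µm/px, 17 planes at
0.5 µm (an 8 µm span) over a 3.5 µm section.

**Scene.** Nuclei are polar splats with low-order Fourier contour
irregularity and clumpy chromatin texture; their depths cluster at the
section midplane (a nucleus is comparable in size to the section, so its
center cannot sit at the surface), which also anchors the best-focus
criterion centrally. Stroma is a smooth eosin wash plus fine collagen
grain. Distractors — fibrosis strands, adipocyte voids, lumen rings — are
label-independent, so attention specificity is a falsifiable property.
A positive label shifts nuclear morphology: mean radius by
`15% · morphology_effect` and contour irregularity by
`5% · morphology_effect`.

**Axial class signal.** With `signal_slice_bias` set, tiles carry "signal
granules" pinned to that plane's depth: positive granules are soft
dot-lattices in optical density, negative granules are flat discs with
exactly the same stain mass. In focus the texture is resolvable; defocus
blur smooths the density toward the common mean, so the class difference
exists *only* near the biased plane — a construct whose information a
virtual stack provably cannot carry. Granule radius (0.14·tile), count (2;
3 in the ablation conditions) and contrast (0.45 OD) were chosen with
pixel- and feature-level probes so the granule separates classes at its
plane (probe AUC ≈ 0.9) without out-sharpening the scene bulk, which would
let the best-focus criterion leak the label.

**Misalignment.** Per-slice affine jitter (uniform translation within
±`misalignment_px`, rotation within ±`misalignment_deg` about the tile
center, reflection-filled) with ground-truth transforms returned, so
registration accuracy is measurable exactly.

**What the generator does not emulate.** Photorealistic histology,
pyramidal gigapixel slides, stain variability between labs, scanner noise
statistics, or IHC appearance. Passing tests show the pipeline recovers
signals *of the kinds constructed here* (morphological and axial); they do
not certify clinical performance.

## Preprocessing

Registration estimates each slice's jitter against a reference (default:
the best-focus slice) by phase-correlation translation initialization
followed by Powell refinement of `(tx, ty, θ)` on the central-crop mean
squared error; recovered jitter is the inverse of the fitted correction.
Measured recovery on jitter up to 3 px / 2°: ≤ 0.2 px and ≤ 0.1°, against
tolerances of 0.5 px / 0.3°. Constant slices raise a registration error
naming the slice. Tiling emits cells of a grid anchored at the slide origin
whose center falls inside an ROI polygon. Best focus maximizes the variance
of the Laplacian of the grayscale slice, ties to the lowest index. Label
summaries round percentages half-up to one decimal (313/401 → 78.1).

## Evaluation machinery

Folds are stratified by dealing class-shuffled ids round-robin with a fold
pointer that continues across classes: fold sizes differ by at most one
(401 ids → 81/80/80/80/80) and per-fold class counts are within one of
proportional. The same split drives pretraining and classification, and
every stage returns the specimen ids it consumed; the audit log in each
run report proves the held-out ids are disjoint from both consumption sets.
AUC is Mann-Whitney concordance via midranks (ties count ½), identical to
exhaustive pair counting. Undefined folds (single-class test sets) are
excluded from the mean with a warning. Data-fraction subsets are nested and
stratified per fold (seeded per-class priority prefixes); the reported
`n_cases` is the cohort-scale `⌊fraction · n⌋`.

**Stack-versus-virtual ablation.** For each tile, the virtual twin stacks
progressively blurred copies of the best-focus slice — blurring the central
slice by `σ₀·d/a` composes with the capture PSF to reproduce
`σ(d)` exactly, so the twin *looks* like a real stack but every plane is a
deterministic function of one slice. Study conditions (frozen before the
final runs): 150 specimens per arm, 32 px tiles, 9 planes at 1.5 µm,
granule signal at plane 0, morphology effect zero, 2-fold CV, mean-pool
MIL head with 8-channel integrator, weight decay 0.1, two restarts, five
seeds; the negative control places the signal at the central (best-focus)
plane. The 1.5 µm spacing (12 µm span) replaces the default 0.5 µm because
at desk scale the defocus growth across a 0.5 µm-spaced stack is smaller
than uint8 quantization for the nearest planes — the wider spacing
preserves the construct (signal plane far from best focus) at 32 px.
The ablation uses the frozen randomly initialized encoder rather than a
pretrained one: the contrastive menu includes Gaussian blur, and training
invariance to blur would suppress exactly the defocus-sensitive signal
under study.

## Interpretation

Slice importance computes Grad-CAM at the encoder's final convolutional
stage for the model's predicted class: channel weights are spatial means of
the gradient, maps are rectified and summed over height and width, averaged
over tiles, normalized per specimen, averaged over specimens and
renormalized; the spread is the across-specimen SD. The select-collapse
construction (integrator wired to one plane, kernel size 1) routes > 0.9 of
the mass to that plane and validates the plumbing end to end.

*Known limitation:* Grad-CAM multiplies gradients by activations, so the
desk-scale curves are dominated by the in-focus bulk content; the trained
model's curve does not visibly concentrate on the signal plane even when
its predictions depend on it, and a trained-versus-untrained "flatness"
contrast is not reproducible at this scale. The attribution arithmetic is
verified by construction instead.

Attention heatmaps min-max normalize weights per specimen (all-equal bags
paint 0.5) over tile footprints at their slide origins. The 2D embedding
export wraps a seeded t-SNE with PCA initialization and reports the
silhouette score of the label clusters.

## Numerical core

All networks run on a reverse-mode autodiff over NumPy arrays
(`stackmil.nn`): broadcastable elementwise ops, matmul, conv2d/conv1d via
`sliding_window_view` + `einsum` with explicit kernel-offset scatter for
input gradients, stable log-sum-exp, Adam with optional decoupled weight
decay. Every layer's gradient is checked against central finite differences
in the test suite, and the InfoNCE gradient against a brute-force oracle.
Computation is float64 end to end and fully seeded: every stochastic
component derives its generator from a root seed plus fixed stage tags
(SHA-256 of the tag), so identical configurations reproduce runs bit for
bit — the end-to-end smoke test asserts identical report hashes across two
fresh pipeline runs.

## Problem sizes

Desk-scale runs use 32 px tiles, 5-9 planes, 3-6 tiles per specimen,
encoders of 8-32 channels with 32-dim features, two contrastive epochs over
a capped slice budget, and 30-100 MIL epochs. The cross-validated signal
recovery uses 100 specimens (5 folds); the ablation 150 per arm over five
seeds; the end-to-end smoke run 20 specimens. These sizes keep the full
suite in CPU-minutes while leaving every algorithmic path identical to a
full-scale configuration.
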