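# Methods

## Problem and model

The target structure is a bilateral nerve whose root and ganglion are thick
(easy to segment) and whose three distal branches are thin (prone to
under-segmentation).  The toolkit treats this as binary 3D semantic
segmentation with three coupled components:

1. a lightweight volumetric encoder–decoder (bottleneck residual blocks +
   squeeze-and-excitation channel gating on a V-Net skeleton);
2. a composite objective `ω·dice + (1−ω)·focal`, optionally with
   morphology-derived difficulty weights on the focal term;
3. a two-resolution cascade: coarse localisation at 1 mm, fine segmentation
   of the localised unilateral regions at 0.5 mm, Gaussian-weighted
   sliding-window fusion at both stages.

### Assumptions

* Single bright foreground class on darker textured background; two-class
  softmax head (background, nerve).
* Input volumes are 3D scalar grids with positive per-axis spacing; axis
  order is (z, y, x) everywhere, boxes are half-open, voxel centres sit at
  `origin + index·spacing`.
* The annotated foreground is the union of a thick core and thin appendages,
  so a morphological opening with a small ball separates the two regimes.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| ω (dice/focal balance) | 0.5 | — | equal weighting of the two terms |
| α, γ (focal) | 0.25, 2 | — | standard focal-loss settings |
| λ₁ / λ₂ (inside/outside Ω) | 0.5 / 1.5 | — | larger weight on the thin, hard region; exact values are a free design choice exposed in `LossConfig` |
| opening radius | 2 | voxels (fine grid) | at 0.5 mm this removes tubes thinner than ~2 mm diameter — the branch calibre — while the root (radius ≥ 3 voxels) survives |
| ε (dice stabiliser) | 1e−5 | — | avoids 0/0 for empty classes; probabilities are clamped to [1e−7, 1−1e−7] before logs |
| levels / base width | 5 / 16 | — | max stride 2⁴ = 16; widths double per level |
| bottleneck reduction r_b | 4 | — | mid-width `out/4` (floor 4 channels) |
| SE reduction r_se | 2 | — | excitation bottleneck |
| learning rate schedule | 1e−4, ×0.1 every 1000 epochs, ≤ 6000 epochs | — | full-scale profile; `lr_at_epoch` implements `lr₀·f^⌊e/interval⌋` |
| coarse / fine spacing | 1.0 / 0.5 | mm | cascade resolutions |
| coarse / fine patch | 128×128×192 / 64×192×160 | voxels | full-scale window sizes |
| window overlap, Gaussian σ | 0.5, patch/8 | — | common 3D fusion practice; the fused map is exactly constant for a constant model regardless |
| ROI padding | 8 | fine voxels | margin added to coarse boxes before fine cropping |
| threshold | 0.5 | — | binarisation at both stages |

### Normalisation

Intensities are clipped to the (0.01, 0.99) percentile window of a region of
interest and mapped affinely to [−1, 1].  When no ROI mask is supplied the
ROI is taken adaptively as voxels above the volume's 10th intensity
percentile.  A `zscore` variant (standardise the clipped values by ROI
mean/SD) is provided because both readings of the published recipe are
defensible; the [−1, 1] map is the default since that is the stated output
range.  Geometric padding and out-of-field filling use −1, the background
level after normalisation.

### Bias-field correction

The default backend is N4 (SimpleITK) on an Otsu foreground mask with
optional pyramid shrinking; the package also ships a self-contained
estimator that fits a degree-3 polynomial to the log-intensity of
above-median voxels and divides out its exponential.  Both are multiplicative
, shape-preserving, and approximately idempotent.

## The phantom generator

Each phantom is built from seeded random-walk centrelines rasterised by a
Euclidean distance test: a thick root tube (radius 3–5 voxels) ends in a
ganglion bulge (root + 2), from which three thinner branches (radius
1.2–1.8, strictly below the opening diameter) walk outward; the structure is
mirrored across the midline for the bilateral case with a guaranteed ≥ 2
voxel gap, so the mask always has exactly two 26-connected components.  The
volume is foreground/background means (200/100, lightly edge-smoothed) plus
smoothed background texture, multiplied by a strictly positive bias field
(exponentiated sum of three random low-frequency cosine modes, ±30 %) with
additive Gaussian noise (σ = 8).  Branch lengths (30–42 steps) were chosen
so the thin region is a non-degenerate 10–60 % of the foreground under the
radius-2 opening.  The generator also exposes per-structure voxel sets; the
"distal branch" set excludes the neighbourhood of the core and of any
locally thick spot (branch crossings or folds, detected by foreground
depth), i.e. exactly the voxels that cannot survive a branch-scale erosion.

What the phantoms emulate: bilateral thick-core/thin-branch geometry,
anisotropic-capable grids, bias fields, noise, and the easy/hard asymmetry
the weighted loss targets.  What they do not: real MR contrast and artefact
statistics, anatomical shape priors, inter-rater annotation noise.  Passing
tests therefore demonstrate the correctness and the qualitative mechanisms
of the implementation, not clinical-grade accuracy.

## Numerical and design choices

* **Autodiff engine.**  The networks run on a compact reverse-mode autodiff
  engine written on NumPy (float32, dynamic graph, im2col convolutions via
  `tensordot`).  All operator gradients are finite-difference checked in the
  test suite.  Adam is the optimizer throughout.
* **Blocks.**  SE gating is applied to the bottleneck stack output before
  the residual addition (standard SE-ResNet placement); shortcuts are
  identity, or 1×1×1 projections on width change.  Instance normalisation +
  PReLU by default; both configurable (`norm="none"`, `activation="relu"`)
  since published parameter counts depend on unstated choices.
* **Exact widths/depths are reconstructions.**  Defaults: widths
  (16, 32, 64, 128, 256), encoder blocks (1, 2, 3, 3, 3), decoder blocks
  (3, 3, 2, 1).  The stride structure (16) and the bottleneck/SE mechanics
  are the fixed design; the complexity reporter exists precisely to audit
  any chosen configuration (the default is ≈ 1.8 M parameters versus
  ≈ 10 M for the plain-convolution variant at identical widths).
* **Loss reductions.**  Focal-family losses are means over all voxels; the
  region weights enter as a per-voxel weight map (λ₁ inside, λ₂ outside,
  1 on background), so with λ₁ = λ₂ = 1 the weighted focal loss is exactly
  the plain one and background false positives always keep unit weight.
  Region splits are recomputed on each cropped patch during training.
* **Degenerate inputs.**  Constant volumes normalise to zeros with a
  warning; empty masks split into two empty regions; an empty coarse
  localisation returns an empty segmentation with a warning; both-empty
  masks score DSC 1.0 while zero-denominator precision/sensitivity are
  reported as undefined and excluded (with counts) from aggregates.
* **Ties and ordering.**  Even-count median spacing takes the lower median
  (stays an observed spacing); ROI instances are ordered by size then box
  start; overlapping fine-stage ROI claims are merged by logical OR.

## Desk-scale profiles

Full-scale training (6000 epochs, 128³-scale patches) is a datacentre
workload, so tests and the acceptance script use a desk profile chosen to
exercise identical code paths in CPU-minutes: 3 levels, base width 8, 32³
patches, Adam at 1e−3, batch 2, foreground-biased sampling 0.5.  Problem
sizes used by the shipped experiments: single-phantom overfit (150
iterations), cascade plumbing with ground-truth-emitting stub models
(oracle replaces the network, isolating resampling/fusion loss), a
6-train/3-test cohort for the acceptance script (40 epochs), and a
12-phantom twin-training comparison (8 train / 4 held-out, 120 iterations,
3 seeds) that measures branch-region sensitivity under the weighted versus
unweighted composite.

## Known limitations

* The NumPy engine is single-device and unoptimised for large batches; the
  full-scale profile is defined but not practical without hours of CPU time.
* Nearest-neighbour resampling (used for both images and masks, matching
  the method's stated choice) aliases thin structures at coarse spacing;
  the cascade mitigates this by padding ROI boxes before fine cropping.
* The phantom's intensity model is Gaussian; no Rician noise or
  partial-volume modelling beyond light smoothing.
* Empty-mask metric conventions follow common benchmark practice and are
  configurable only in code.
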