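# nerveseg

Coarse-to-fine 3D semantic segmentation of thin tubular nerve structures in
MR volumes, built for the trigeminal nerve problem: the nerve's root and
ganglion are thick and easy to segment, while its three distal branches
(ophthalmic, maxillary, mandibular) are thin and chronically
under-segmented.  `nerveseg` packages the full method — preprocessing,
a lightweight attention V-Net, difficulty-weighted composite losses, a
two-resolution cascade with Gaussian sliding-window fusion, and evaluation —
together with a synthetic phantom generator so every stage runs and is
testable without clinical data.

## Who it is for

Researchers in medical image analysis who want a small, dependency-light,
fully inspectable reference implementation of this segmentation recipe —
including a pure-NumPy autodiff engine (`nerveseg.nn`), so the whole
pipeline trains on a single CPU.

## The method

**Architecture.** A V-Net-style 3D encoder–decoder (5 levels, max stride
2⁴ = 16) whose convolution blocks are *bottleneck residual blocks* — 1×1×1
reduce, 3×3×3 process at width C/r_b, 1×1×1 restore, plus a shortcut — with
*squeeze-and-excitation* channel gating (global average pool → FC → FC →
sigmoid → channel rescale).  Both changes cut parameters by roughly an order
of magnitude versus plain 3×3×3 blocks at the same widths (see
`report-complexity`).

**Losses.** With per-voxel class probabilities `p_c(i)` and one-hot labels
`g_c(i)`:

    L_dice  = 1 − (1/C) Σ_c [ 2 Σ_i p_c(i) g_c(i) / (Σ_i p_c(i)² + Σ_i g_c(i)² + ε) ]
    L_focal = mean_i [ −α_t (1 − p_t)^γ log p_t ],   p_t = p if y=1 else 1−p
    L       = ω·L_dice + (1−ω)·L_focal                       (ω = 0.5)

The region-weighted variant splits the annotated foreground Ω by
morphological opening (discrete ball, radius 2 voxels) into a thick core
(inside Ω) and the thin remainder (outside Ω), and scales the focal terms by
λ₁ inside, λ₂ outside, 1 on background:

    L_ω = ω·L_dice + (1−ω)·[ λ₁·L_focal^{insideΩ} + λ₂·L_focal^{outsideΩ} ]

With λ₂ > λ₁ (defaults 1.5 / 0.5) the optimisation pressure stays on the
thin branches after the thick core is fitted.

**Cascade.** A coarse network at 1 mm isotropic spacing localises the nerve;
connected components of its thresholded output give left/right bounding
boxes; a fine network at 0.5 mm segments each box; overlapping sliding
windows are fused by Gaussian-weighted averaging and pasted back onto the
native grid.

## Worked example

```python
import numpy as np
from nerveseg import PhantomSpec, generate_phantom
from nerveseg.network import NetworkConfig, build_network
from nerveseg.pipeline import TrainConfig, train, sliding_window_predict
from nerveseg.preprocessing import normalize_intensity
from nerveseg.evaluation import confusion_counts, dsc

vol, mask = generate_phantom(PhantomSpec(seed=1))   # bilateral nerve phantom
dataset = [(normalize_intensity(vol), mask)]
model = build_network(NetworkConfig(levels=3, base_width=8), seed=0)
cfg = TrainConfig(learning_rate=1e-3, max_epochs=150, batch_size=2,
                  patch_size=(32, 32, 32), validation_fraction=0.0, seed=0)
model, hist = train(model, dataset, "omega_double", cfg)
print(f"loss {hist.loss[0]:.3f} -> {hist.loss[-1]:.3f}")
probs = sliding_window_predict(model, dataset[0][0].data, (32, 32, 32))
pred = (probs[1] >= 0.5).astype(np.uint8)
print(f"train DSC {dsc(confusion_counts(pred, mask.data)):.3f}")
```

prints (desk profile, one CPU, ~1 minute):

```
loss 0.391 -> 0.013
train DSC 0.927
```

i.e. 150 iterations overfit the single phantom: the composite loss falls by
~30x and the fused full-volume segmentation overlaps the ground truth at
DSC 0.93 — thin-branch tips account for most of the remaining error.

The same flow is available from the shell:

```bash
nerveseg synth --n 12 --out data/ --seed 7
nerveseg train --data data/ --stage fine --out ckpt/fine.npz
nerveseg report-complexity            # parameters / conv layers / GMac row
```

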