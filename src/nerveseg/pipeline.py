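"""Training loop, sliding-window inference and the coarse-to-fine cascade.

Training follows a step-decay learning-rate schedule (initial 1e-4, x0.1
every 1000 epochs, up to 6000 epochs by default — the full-scale profile) and
keeps the checkpoint with the best validation DSC.  Inference tiles a volume
with overlapping patches whose predictions are fused by Gaussian-weighted
averaging, so window centres dominate and tile seams vanish.

The cascade runs two resolutions: a coarse network on the volume resampled to
1 mm localises the nerve (connected components of the thresholded prediction
give padded bounding boxes), then a fine network at 0.5 mm segments each
unilateral ROI; ROI predictions are mapped back to the native grid and merged
by logical OR.

The desk profile (small widths, 3 levels, 32 voxel patches, a few hundred
iterations) makes the whole cascade trainable on one CPU in minutes; the
full-scale profile mirrors the deployment geometry (5 levels, patch
128x128x192 coarse / 64x192x160 fine).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .augmentation import AugmentConfig, augment
from .core_io import BoundingBox, Mask, Volume
from .losses import LossConfig, RegionSplit, make_loss, split_difficulty_regions
from .network import NetworkConfig, SegmentationNet, build_network
from .preprocessing import (
    correct_bias_field,
    normalize_intensity,
    random_crop,
    resample,
    resize_nearest,
    split_connected_rois,
)

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "CascadeModel",
    "lr_at_epoch",
    "train",
    "sliding_window_predict",
    "coarse_localize",
    "cascade_predict",
    "GroundTruthOracle",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation schedule and sampling settings.

    The defaults are the full-scale profile: initial learning rate 1e-4
    decayed by 0.1 every 1000 epochs for up to 6000 epochs, best checkpoint
    selected by validation DSC.  Desk-scale runs override ``max_epochs``,
    ``learning_rate`` and ``patch_size``.
    """

    learning_rate: float = 1e-4
    decay_factor: float = 0.1
    decay_interval: int = 1000
    max_epochs: int = 6000
    batch_size: int = 2
    patch_size: Tuple[int, int, int] = (64, 192, 160)
    foreground_prob: float = 0.5
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if not 0 < self.decay_factor <= 1:
            raise ValueError("decay factor must be in (0, 1]")
        if self.max_epochs < 1 or self.decay_interval < 1:
            raise ValueError("epoch counts must be >= 1")


@dataclass
class TrainHistory:
    loss: List[float] = field(default_factory=list)
    val_dsc: List[float] = field(default_factory=list)
    lr: List[float] = field(default_factory=list)
    best_epoch: int = -1


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Step-decay schedule: ``lr0 * factor ** floor(epoch / interval)``."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return config.learning_rate * config.decay_factor ** (epoch // config.decay_interval)


def _one_hot(mask_patch: np.ndarray) -> np.ndarray:
    fg = mask_patch.astype(np.float32)
    return np.stack([1.0 - fg, fg])


def _patch_dsc(pred_fg: np.ndarray, truth: np.ndarray) -> float:
    p = pred_fg >= 0.5
    t = truth.astype(bool)
    denom = p.sum() + t.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, t).sum() / denom)


def train(
    model: SegmentationNet,
    dataset: Sequence[Tuple[Volume, Mask]],
    loss_name: str = "omega_double",
    config: TrainConfig = TrainConfig(),
    loss_config: LossConfig = LossConfig(),
    augment_config: Optional[AugmentConfig] = None,
) -> Tuple[SegmentationNet, TrainHistory]:
    """Train a network on (volume, mask) pairs; return best model + history.

    Per iteration: seeded random crop -> optional augmentation -> forward ->
    loss -> Adam step.  One epoch is one pass over the training cases
    (``batch_size`` patches per step).  The model state with the best
    validation DSC is restored before returning; with fewer than one
    validation case the training-patch DSC is used for selection.
    Raises on an empty dataset and aborts with a diagnostic on a
    non-finite loss.
    """
    if len(dataset) == 0:
        raise ValueError("dataset must not be empty")
    rng = np.random.default_rng(config.seed)
    n_val = int(round(config.validation_fraction * len(dataset)))
    n_val = min(n_val, len(dataset) - 1)
    order = rng.permutation(len(dataset))
    val_idx = list(order[:n_val])
    train_idx = list(order[n_val:])

    loss_fn = make_loss(loss_name, loss_config)
    needs_split = loss_name.lower() in ("omega_double", "wdouble", "omegadoubleloss")
    optimizer = nn.Adam(model.parameters(), lr=config.learning_rate)
    history = TrainHistory()
    best_state: Optional[dict] = None
    best_dsc = -1.0
    iteration = 0

    for epoch in range(config.max_epochs):
        optimizer.lr = lr_at_epoch(config, epoch)
        epoch_losses = []
        case_order = list(rng.permutation(train_idx))
        # wrap so every optimisation step sees a full batch (a case may
        # contribute more than one patch when the dataset is small)
        while len(case_order) % config.batch_size:
            case_order.append(int(rng.choice(train_idx)))
        for start in range(0, len(case_order), config.batch_size):
            batch_cases = case_order[start : start + config.batch_size]
            xs, ys, insides, outsides = [], [], [], []
            for ci in batch_cases:
                vol, msk = dataset[ci]
                crop_seed = int(rng.integers(2**31 - 1))
                vp, mp = random_crop(vol, msk, config.patch_size, crop_seed, config.foreground_prob)
                if augment_config is not None:
                    vp, mp = augment(vp, mp, augment_config, int(rng.integers(2**31 - 1)))
                xs.append(vp)
                ys.append(_one_hot(mp))
                if needs_split:
                    # difficulty split recomputed on the cropped patch labels
                    sp = split_difficulty_regions(mp, loss_config.morph_radius)
                    insides.append(sp.inside)
                    outsides.append(sp.outside)
            x = np.stack(xs)[:, None].astype(np.float32)
            y = np.stack(ys).astype(np.float32)
            split = None
            if needs_split:
                split = RegionSplit(np.stack(insides), np.stack(outsides),
                                    np.stack(insides) | np.stack(outsides))
            probs = model.forward(x)
            loss = loss_fn(probs, y, split)
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise RuntimeError(f"non-finite loss at iteration {iteration} (epoch {epoch})")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(lval)
            iteration += 1

        # validation: one deterministic foreground-centred patch per case
        eval_idx = val_idx if val_idx else train_idx
        dscs = []
        for ci in eval_idx:
            vol, msk = dataset[ci]
            vp, mp = random_crop(vol, msk, config.patch_size, seed=ci, foreground_prob=1.0)
            probs = model.forward(vp[None, None].astype(np.float32))
            dscs.append(_patch_dsc(probs.data[0, 1], mp))
        val_dsc = float(np.mean(dscs))

        history.loss.append(float(np.mean(epoch_losses)))
        history.val_dsc.append(val_dsc)
        history.lr.append(optimizer.lr)
        if val_dsc > best_dsc:
            best_dsc = val_dsc
            best_state = model.state_dict()
            history.best_epoch = epoch

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


# ---------------------------------------------------------------------------
# sliding-window inference
# ---------------------------------------------------------------------------


def _gaussian_weights(patch_size: Sequence[int], sigma_scale: float) -> np.ndarray:
    ws = []
    for n in patch_size:
        x = np.arange(n) - (n - 1) / 2.0
        sig = max(1e-6, sigma_scale * n)
        ws.append(np.exp(-0.5 * (x / sig) ** 2))
    return ws[0][:, None, None] * ws[1][None, :, None] * ws[2][None, None, :]


def _window_starts(dim: int, patch: int, step: int) -> List[int]:
    if dim <= patch:
        return [0]
    starts = list(range(0, dim - patch + 1, step))
    if starts[-1] != dim - patch:
        starts.append(dim - patch)
    return starts


def sliding_window_predict(
    model,
    volume: np.ndarray,
    patch_size: Sequence[int],
    overlap: float = 0.5,
    sigma_scale: float = 0.125,
    pad_value: Optional[float] = None,
    grid_origin: Optional[Sequence[float]] = None,
    grid_spacing: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Tile ``volume`` (3D array) with overlapping patches and fuse softly.

    Per voxel the output is ``sum_w w * p / sum_w w`` over the covering
    windows, with ``w`` a separable Gaussian centred in each window
    (sigma = ``sigma_scale`` x patch edge).  Axes shorter than the patch are
    padded with ``pad_value`` (default: volume minimum) and cropped back, so
    a patch larger than the volume is never an error.  Returns the per-class
    probability grid ``(C, Z, Y, X)`` with class sums 1 everywhere.

    ``grid_origin``/``grid_spacing`` (mm) describe the physical placement of
    ``volume`` and are forwarded to location-aware models (see
    :class:`GroundTruthOracle`).
    """
    patch = tuple(int(p) for p in patch_size)
    vol = np.asarray(volume, dtype=np.float32)
    fill = float(vol.min()) if pad_value is None else float(pad_value)
    pads = [(max(0, p - n) // 2, max(0, p - n) - max(0, p - n) // 2) for n, p in zip(vol.shape, patch)]
    padded = np.pad(vol, pads, constant_values=fill) if any(a or b for a, b in pads) else vol

    step = [max(1, int(round(p * (1.0 - overlap)))) for p in patch]
    starts = [_window_starts(n, p, s) for n, p, s in zip(padded.shape, patch, step)]
    weights = _gaussian_weights(patch, sigma_scale)

    location_aware = bool(getattr(model, "location_aware", False))
    acc: Optional[np.ndarray] = None
    wsum = np.zeros(padded.shape, dtype=np.float64)
    for sz in starts[0]:
        for sy in starts[1]:
            for sx in starts[2]:
                sl = (slice(sz, sz + patch[0]), slice(sy, sy + patch[1]), slice(sx, sx + patch[2]))
                patch_in = padded[sl][None, None]
                if location_aware:
                    origin = None
                    if grid_origin is not None and grid_spacing is not None:
                        origin = tuple(
                            o + (s - p0) * sp
                            for o, s, p0, sp in zip(
                                grid_origin, (sz, sy, sx), [a for a, _ in pads], grid_spacing
                            )
                        )
                    probs = model(patch_in, origin_mm=origin, spacing=grid_spacing)
                else:
                    probs = model(patch_in)
                p = probs.data if isinstance(probs, nn.Tensor) else np.asarray(probs)
                p = p[0]  # (C, pz, py, px)
                if acc is None:
                    acc = np.zeros((p.shape[0],) + padded.shape, dtype=np.float64)
                acc[(slice(None),) + sl] += weights * p
                wsum[sl] += weights
    fused = acc / wsum
    crop = tuple(slice(a, a + n) for (a, _), n in zip(pads, vol.shape))
    return fused[(slice(None),) + crop].astype(np.float32)


class GroundTruthOracle:
    """Location-aware stub model that emits ground-truth probabilities.

    Used to isolate cascade plumbing loss (resampling, cropping, fusion,
    coordinate mapping) from model loss: for any requested window it samples
    the reference mask at the window's physical voxel centres (nearest
    neighbour) and returns the corresponding one-hot probabilities.
    """

    location_aware = True

    def __init__(self, mask: Mask):
        self.mask = mask

    def __call__(self, patch: np.ndarray, origin_mm=None, spacing=None) -> np.ndarray:
        if origin_mm is None or spacing is None:
            raise ValueError("GroundTruthOracle needs window origin and spacing")
        shape = patch.shape[2:]
        idx = []
        for ax, n in enumerate(shape):
            centers = origin_mm[ax] + np.arange(n) * spacing[ax]
            src = np.round((centers - self.mask.origin[ax]) / self.mask.spacing[ax]).astype(int)
            idx.append(np.clip(src, 0, self.mask.shape[ax] - 1))
        fg = self.mask.data[np.ix_(*idx)].astype(np.float32)
        return np.stack([1.0 - fg, fg])[None]


# ---------------------------------------------------------------------------
# coarse-to-fine cascade
# ---------------------------------------------------------------------------


@dataclass
class CascadeModel:
    """Paired coarse/fine models plus their resampling and fusion settings."""

    coarse_model: object
    fine_model: object
    coarse_spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    fine_spacing: Tuple[float, float, float] = (0.5, 0.5, 0.5)
    coarse_patch: Tuple[int, int, int] = (128, 128, 192)
    fine_patch: Tuple[int, int, int] = (64, 192, 160)
    overlap: float = 0.5
    sigma_scale: float = 0.125
    roi_pad_voxels: int = 8
    min_component_voxels: int = 30
    bias_correct: bool = True
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not all(c > f for c, f in zip(self.coarse_spacing, self.fine_spacing)):
            raise ValueError("coarse spacing must be larger than fine spacing")


def coarse_localize(
    coarse_volume: Volume,
    model,
    min_component_voxels: int = 30,
    *,
    patch_size: Sequence[int] = (128, 128, 192),
    overlap: float = 0.5,
    sigma_scale: float = 0.125,
    pad_voxels: int = 8,
    native_shape: Optional[Sequence[int]] = None,
    native_spacing: Optional[Sequence[float]] = None,
    threshold: float = 0.5,
) -> List[BoundingBox]:
    """Localise nerve candidates on the coarse grid.

    Thresholds the fused foreground probability, splits it into connected
    components (dropping those below ``min_component_voxels``) and returns
    their padded bounding boxes — mapped to native-resolution coordinates
    when ``native_shape``/``native_spacing`` are given.  Padding is applied
    in native voxels.  Returns an empty list (with a warning) when nothing
    exceeds the threshold.
    """
    probs = sliding_window_predict(
        model,
        coarse_volume.data,
        patch_size,
        overlap,
        sigma_scale,
        grid_origin=coarse_volume.origin,
        grid_spacing=coarse_volume.spacing,
    )
    fg = (probs[-1] >= threshold).astype(np.uint8)
    if not fg.any():
        warnings.warn("coarse stage found no foreground", stacklevel=2)
        return []
    rois = split_connected_rois(Mask(fg, coarse_volume.spacing, coarse_volume.origin),
                               min_voxels=min_component_voxels)
    if not rois:
        warnings.warn("all coarse components below the size threshold", stacklevel=2)
        return []
    boxes = []
    for roi in rois:
        if native_shape is None or native_spacing is None:
            boxes.append(roi.box.padded(pad_voxels, coarse_volume.shape))
            continue
        start, stop = [], []
        for ax in range(3):
            ratio = coarse_volume.spacing[ax] / native_spacing[ax]
            a = int(np.floor(roi.box.start[ax] * ratio)) - pad_voxels
            b = int(np.ceil(roi.box.stop[ax] * ratio)) + pad_voxels
            start.append(max(0, a))
            stop.append(min(int(native_shape[ax]), max(b, a + 1)))
        boxes.append(BoundingBox(tuple(start), tuple(stop)))
    return boxes


def cascade_predict(volume: Volume, cascade: CascadeModel) -> Mask:
    """Run the full coarse-to-fine pipeline on a raw native-resolution volume.

    Preprocess (optional bias correction, resample to the coarse spacing,
    normalise), localise ROIs with the coarse model, then for each ROI crop
    the native volume, resample to the fine spacing, normalise and run
    sliding-window prediction with the fine model; thresholded ROI masks are
    resized back onto the native grid and merged by logical OR.  An empty
    localisation yields an empty mask with a warning.
    """
    work = correct_bias_field(volume) if cascade.bias_correct else volume
    coarse_vol = normalize_intensity(resample(work, cascade.coarse_spacing))
    boxes = coarse_localize(
        coarse_vol,
        cascade.coarse_model,
        cascade.min_component_voxels,
        patch_size=cascade.coarse_patch,
        overlap=cascade.overlap,
        sigma_scale=cascade.sigma_scale,
        pad_voxels=cascade.roi_pad_voxels,
        native_shape=volume.shape,
        native_spacing=volume.spacing,
        threshold=cascade.threshold,
    )
    out = np.zeros(volume.shape, dtype=np.uint8)
    if not boxes:
        warnings.warn("cascade produced an empty segmentation", stacklevel=2)
        return Mask(out, volume.spacing, volume.origin)
    for box in boxes:
        crop_origin = tuple(
            o + s * sp for o, s, sp in zip(work.origin, box.start, work.spacing)
        )
        crop = Volume(work.data[box.slices], work.spacing, crop_origin)
        fine_vol = normalize_intensity(resample(crop, cascade.fine_spacing))
        probs = sliding_window_predict(
            cascade.fine_model,
            fine_vol.data,
            cascade.fine_patch,
            cascade.overlap,
            cascade.sigma_scale,
            grid_origin=fine_vol.origin,
            grid_spacing=fine_vol.spacing,
        )
        roi_mask = (probs[-1] >= cascade.threshold).astype(np.uint8)
        native_roi = resize_nearest(roi_mask, box.shape)
        out[box.slices] |= native_roi
    return Mask(out, volume.spacing, volume.origin)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: SegmentationNet, path) -> None:
    """Weights as .npz plus a JSON sidecar with the network configuration."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    from dataclasses import asdict

    sidecar = Path(str(path) + ".json" if not path.suffix == ".npz" else str(path.with_suffix(".json")))
    cfg = asdict(model.config)
    sidecar.write_text(json.dumps(cfg, indent=2))


def load_checkpoint(path) -> SegmentationNet:
    path = Path(path)
    sidecar = path.with_suffix(".json")
    cfg_dict = json.loads(sidecar.read_text())
    for key in ("encoder_blocks", "decoder_blocks"):
        if cfg_dict.get(key) is not None:
            cfg_dict[key] = tuple(cfg_dict[key])
    model = build_network(NetworkConfig(**cfg_dict))
    state = dict(np.load(path))
    model.load_state_dict(state)
    return model
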