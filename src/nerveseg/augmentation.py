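"""Seeded geometric and intensity augmentation of (volume, mask) patch pairs.

Geometric transforms (mirror, rotation/scaling/translation as one affine,
elastic deformation) are applied identically to both patch members — the
volume with trilinear interpolation, the mask with nearest-neighbour so it
stays binary.  Intensity transforms (brightness, gamma, cover boxes, noise,
blur) touch only the volume.  Every application is resolved into a replayable
:class:`TransformRecord` first, so any augmented sample can be reproduced
exactly from its record.

Out-of-field voxels created by geometric transforms are filled with the
configured background value (-1, the background level after [-1, 1]
normalisation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

__all__ = ["AugmentConfig", "TransformRecord", "sample_transform", "apply_record", "augment"]


@dataclass(frozen=True)
class AugmentConfig:
    """Per-transform enable probabilities and parameter ranges.

    Defaults are conventional light augmentation for 3D MR patches; ranges
    are uniform-draw bounds, probabilities independent per transform.
    """

    p_mirror: float = 0.2
    mirror_axes: Tuple[int, ...] = (0, 1, 2)
    p_rotation: float = 0.2
    rotation_deg: Tuple[float, float] = (-15.0, 15.0)
    p_scaling: float = 0.2
    scale_range: Tuple[float, float] = (0.85, 1.15)
    p_translation: float = 0.2
    translation_vox: Tuple[float, float] = (-5.0, 5.0)
    p_elastic: float = 0.2
    elastic_spacing: int = 16
    elastic_sigma: float = 2.0
    p_brightness: float = 0.2
    brightness_range: Tuple[float, float] = (-0.1, 0.1)
    p_gamma: float = 0.2
    gamma_range: Tuple[float, float] = (0.8, 1.25)
    p_cover: float = 0.2
    cover_boxes: Tuple[int, int] = (1, 3)
    cover_max_frac: float = 0.1
    p_noise: float = 0.2
    noise_sigma: Tuple[float, float] = (0.0, 0.1)
    p_blur: float = 0.2
    blur_sigma: Tuple[float, float] = (0.5, 1.0)
    fill_value: float = -1.0

    def __post_init__(self) -> None:
        for name in ("rotation_deg", "scale_range", "translation_vox", "gamma_range",
                     "brightness_range", "noise_sigma", "blur_sigma", "cover_boxes"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range inverted: ({lo}, {hi})")
        for name, p in (("p_mirror", self.p_mirror), ("p_rotation", self.p_rotation),
                        ("p_scaling", self.p_scaling), ("p_translation", self.p_translation),
                        ("p_elastic", self.p_elastic), ("p_brightness", self.p_brightness),
                        ("p_gamma", self.p_gamma), ("p_cover", self.p_cover),
                        ("p_noise", self.p_noise), ("p_blur", self.p_blur)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class TransformRecord:
    """Fully resolved parameters of one augmentation draw (for replay/logging)."""

    mirror_axes: Tuple[int, ...] = ()
    rotation_deg: Optional[Tuple[float, float, float]] = None
    scale: Optional[float] = None
    translation: Optional[Tuple[float, float, float]] = None
    elastic: Optional[dict] = None  # {"seed", "spacing", "sigma"}
    brightness: Optional[float] = None
    gamma: Optional[float] = None
    cover: Optional[List[Tuple[Tuple[int, int, int], Tuple[int, int, int]]]] = None
    noise: Optional[dict] = None  # {"sigma", "seed"}
    blur_sigma: Optional[float] = None
    fill_value: float = -1.0

    def applied(self) -> List[str]:
        out = []
        for name in ("mirror_axes", "rotation_deg", "scale", "translation", "elastic",
                     "brightness", "gamma", "cover", "noise", "blur_sigma"):
            v = getattr(self, name)
            if v not in (None, (), []):
                out.append(name)
        return out


def sample_transform(config: AugmentConfig, seed: int) -> TransformRecord:
    """Draw a concrete transform record from the configured ranges."""
    rng = np.random.default_rng(seed)
    rec = TransformRecord(fill_value=config.fill_value)
    if rng.random() < config.p_mirror:
        axes = tuple(ax for ax in config.mirror_axes if rng.random() < 0.5)
        rec.mirror_axes = axes
    if rng.random() < config.p_rotation:
        rec.rotation_deg = tuple(rng.uniform(*config.rotation_deg) for _ in range(3))
    if rng.random() < config.p_scaling:
        rec.scale = float(rng.uniform(*config.scale_range))
    if rng.random() < config.p_translation:
        rec.translation = tuple(rng.uniform(*config.translation_vox) for _ in range(3))
    if rng.random() < config.p_elastic:
        rec.elastic = {
            "seed": int(rng.integers(2**31 - 1)),
            "spacing": int(config.elastic_spacing),
            "sigma": float(config.elastic_sigma),
        }
    if rng.random() < config.p_brightness:
        rec.brightness = float(rng.uniform(*config.brightness_range))
    if rng.random() < config.p_gamma:
        rec.gamma = float(rng.uniform(*config.gamma_range))
    if rng.random() < config.p_cover:
        rec.cover = []  # boxes resolved against the patch shape at apply time
        n_boxes = int(rng.integers(config.cover_boxes[0], config.cover_boxes[1] + 1))
        rec.cover = [("pending", int(rng.integers(2**31 - 1)), n_boxes, config.cover_max_frac)]
    if rng.random() < config.p_noise:
        rec.noise = {
            "sigma": float(rng.uniform(*config.noise_sigma)),
            "seed": int(rng.integers(2**31 - 1)),
        }
    if rng.random() < config.p_blur:
        rec.blur_sigma = float(rng.uniform(*config.blur_sigma))
    return rec


def _rotation_matrix(deg: Tuple[float, float, float]) -> np.ndarray:
    rz, ry, rx = [np.deg2rad(d) for d in deg]
    cz, sz = np.cos(rz), np.sin(rz)
    cy, sy = np.cos(ry), np.sin(ry)
    cx, sx = np.cos(rx), np.sin(rx)
    # rotations about the three array axes, composed
    m0 = np.array([[1, 0, 0], [0, cz, -sz], [0, sz, cz]])
    m1 = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    m2 = np.array([[cx, -sx, 0], [sx, cx, 0], [0, 0, 1]])
    return m0 @ m1 @ m2


def _apply_affine(vol, msk, rec: TransformRecord):
    mat = np.eye(3)
    if rec.rotation_deg is not None:
        mat = mat @ _rotation_matrix(rec.rotation_deg)
    if rec.scale is not None:
        mat = mat / rec.scale  # output-to-input mapping: zoom-in = smaller matrix
    shift = np.zeros(3)
    if rec.translation is not None:
        shift = -np.asarray(rec.translation)
    center = (np.asarray(vol.shape) - 1) / 2.0
    offset = center - mat @ center + shift
    vol = ndimage.affine_transform(vol, mat, offset=offset, order=1, mode="constant",
                                   cval=rec.fill_value)
    msk = ndimage.affine_transform(msk, mat, offset=offset, order=0, mode="constant", cval=0)
    return vol, msk


def _apply_elastic(vol, msk, rec: TransformRecord):
    e = rec.elastic
    rng = np.random.default_rng(e["seed"])
    ctrl_shape = tuple(max(2, int(np.ceil(n / e["spacing"])) + 1) for n in vol.shape)
    coords = np.indices(vol.shape).astype(np.float64)
    for axis in range(3):
        ctrl = rng.normal(0.0, e["sigma"], size=ctrl_shape)
        disp = ndimage.zoom(ctrl, [n / c for n, c in zip(vol.shape, ctrl_shape)], order=3)
        coords[axis] += disp[: vol.shape[0], : vol.shape[1], : vol.shape[2]]
    vol = ndimage.map_coordinates(vol, coords, order=1, mode="constant", cval=rec.fill_value)
    msk = ndimage.map_coordinates(msk, coords, order=0, mode="constant", cval=0)
    return vol, msk


def _resolve_cover(rec: TransformRecord, shape) -> List[Tuple[Tuple[int, ...], Tuple[int, ...]]]:
    tag, seed, n_boxes, max_frac = rec.cover[0]
    if tag != "pending":  # already resolved (replay)
        return rec.cover
    rng = np.random.default_rng(seed)
    boxes = []
    max_len = [max(1, int(round(n * max_frac ** (1 / 3)))) for n in shape]
    for _ in range(n_boxes):
        size = tuple(int(rng.integers(1, m + 1)) for m in max_len)
        start = tuple(int(rng.integers(0, n - s + 1)) for n, s in zip(shape, size))
        boxes.append((start, size))
    return boxes


def apply_record(volume_patch: np.ndarray, mask_patch: np.ndarray, rec: TransformRecord):
    """Apply a resolved transform record to an aligned patch pair."""
    vol = np.asarray(volume_patch, dtype=np.float32).copy()
    msk = np.asarray(mask_patch).astype(np.uint8).copy()
    if vol.shape != msk.shape:
        raise ValueError("volume and mask patches misaligned")

    for ax in rec.mirror_axes:
        vol = np.flip(vol, axis=ax)
        msk = np.flip(msk, axis=ax)
    if rec.rotation_deg is not None or rec.scale is not None or rec.translation is not None:
        vol, msk = _apply_affine(vol, msk, rec)
    if rec.elastic is not None:
        vol, msk = _apply_elastic(vol, msk, rec)

    if rec.brightness is not None:
        vol = vol + rec.brightness
    if rec.gamma is not None:
        lo, hi = float(vol.min()), float(vol.max())
        if hi > lo:
            unit = (vol - lo) / (hi - lo)
            vol = unit ** rec.gamma * (hi - lo) + lo
    if rec.cover is not None:
        for start, size in _resolve_cover(rec, vol.shape):
            sl = tuple(slice(s, s + z) for s, z in zip(start, size))
            vol[sl] = rec.fill_value
    if rec.noise is not None and rec.noise["sigma"] > 0:
        nrng = np.random.default_rng(rec.noise["seed"])
        vol = vol + nrng.normal(0.0, rec.noise["sigma"], vol.shape)
    if rec.blur_sigma is not None:
        vol = ndimage.gaussian_filter(vol, rec.blur_sigma)

    return np.ascontiguousarray(vol, dtype=np.float32), np.ascontiguousarray(msk)


def augment(
    volume_patch: np.ndarray,
    mask_patch: np.ndarray,
    config: AugmentConfig,
    seed: int,
):
    """Sample a transform from ``config`` with the given seed and apply it."""
    rec = sample_transform(config, seed)
    vol, msk = apply_record(volume_patch, mask_patch, rec)
    return vol, msk
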