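"""Segmentation objectives: dice, focal, their blend, and the region-weighted
variant driven by a morphological easy/hard split.

The composite loss is ``L = w * L_dice + (1 - w) * L_focal`` with balance
``w`` (default 0.5).  The region-weighted variant replaces the focal term by
a spatially weighted one: the annotated foreground Omega is split by
morphological opening into a thick core ("inside", easy to segment) and the
thin remainder ("outside", the branches prone to under-segmentation), and the
per-voxel focal terms are scaled by ``lambda1`` inside, ``lambda2`` outside
and 1 on background.  Choosing ``lambda2 > lambda1`` keeps the optimisation
pressure on the thin branches after the thick core is already well fitted.

All loss functions are duck-typed: they accept plain NumPy arrays (returning
a float, used by tests and evaluation) or autodiff tensors (returning a
scalar tensor, used in training).  Labels, weights and region masks are
always plain arrays — only predictions carry gradients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import ndimage

from .core_io import Mask
from .nn import Tensor

__all__ = [
    "LossConfig",
    "RegionSplit",
    "dice_loss",
    "focal_loss",
    "double_loss",
    "split_difficulty_regions",
    "weighted_focal_loss",
    "omega_double_loss",
    "make_loss",
]

_P_CLIP = (1e-7, 1.0 - 1e-7)


@dataclass(frozen=True)
class LossConfig:
    """Parameters of the composite objectives.

    omega: dice/focal balance in [0, 1].  alpha, gamma: focal class weight and
    modulating exponent.  lambda1/lambda2: inside/outside region weights (the
    defaults put 3x more weight on the thin region than the core).  eps
    stabilises dice denominators; morph_radius (voxels) is the opening ball.
    """

    omega: float = 0.5
    alpha: float = 0.25
    gamma: float = 2.0
    lambda1: float = 0.5
    lambda2: float = 1.5
    eps: float = 1e-5
    morph_radius: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError("omega must be in [0, 1]")
        if self.gamma < 0 or self.lambda1 < 0 or self.lambda2 < 0 or self.eps <= 0:
            raise ValueError("gamma/lambda1/lambda2 must be >= 0 and eps > 0")


@dataclass
class RegionSplit:
    """Disjoint partition of a foreground mask into easy core and hard remainder."""

    inside: np.ndarray
    outside: np.ndarray
    source: np.ndarray

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside, dtype=bool)
        self.outside = np.asarray(self.outside, dtype=bool)
        self.source = np.asarray(self.source, dtype=bool)
        if (self.inside & self.outside).any():
            raise ValueError("inside and outside regions overlap")
        if not np.array_equal(self.inside | self.outside, self.source):
            raise ValueError("inside | outside must equal the source foreground")


def ball_structure(radius: int) -> np.ndarray:
    """Discrete Euclidean ball of the given voxel radius."""
    r = int(radius)
    zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return zz * zz + yy * yy + xx * xx <= r * r


def split_difficulty_regions(
    mask: Union[Mask, np.ndarray],
    radius_voxels: int = 2,
    structure: Optional[np.ndarray] = None,
) -> RegionSplit:
    """Split foreground into a thick core and thin remainder by opening.

    ``inside`` is the morphological opening of the foreground with a discrete
    Euclidean ball of ``radius_voxels`` (erosion then dilation — structures
    thinner than about twice the radius vanish, thick ones keep their original
    extent); ``outside`` is the rest of the foreground.  An empty mask yields
    two empty regions.
    """
    if radius_voxels < 1:
        raise ValueError("radius must be >= 1 voxel")
    data = mask.data if isinstance(mask, Mask) else np.asarray(mask)
    fg = data.astype(bool)
    if structure is None:
        structure = ball_structure(radius_voxels)
    if not fg.any():
        empty = np.zeros_like(fg)
        return RegionSplit(empty, empty.copy(), fg)
    inside = ndimage.binary_opening(fg, structure=structure)
    return RegionSplit(inside, fg & ~inside, fg)


# ---------------------------------------------------------------------------
# loss terms (duck-typed over ndarray / Tensor predictions)
# ---------------------------------------------------------------------------


def _is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def _as_float(value, like_tensor: bool):
    if like_tensor:
        return value
    return float(value.data) if _is_tensor(value) else float(value)


def _check_shapes(probs, labels) -> None:
    pshape = probs.shape if not _is_tensor(probs) else probs.shape
    if tuple(pshape) != tuple(np.shape(labels)):
        raise ValueError(f"shape mismatch: probs {tuple(pshape)} vs labels {tuple(np.shape(labels))}")


def dice_loss(probs, labels, eps: float = 1e-5, class_axis: int = 0):
    """Soft multi-class dice loss.

    ``probs`` holds per-class probabilities with classes along ``class_axis``
    (e.g. ``(C, Z, Y, X)`` or batched ``(N, C, Z, Y, X)`` with
    ``class_axis=1``); ``labels`` is the one-hot grid of identical shape.
    Returns ``1 - mean_c [ 2 sum_i p_c(i) g_c(i) / (sum_i p_c(i)^2 +
    sum_i g_c(i)^2 + eps) ]`` where i runs over all non-class axes.
    """
    _check_shapes(probs, labels)
    labels = np.asarray(labels, dtype=np.float64 if not _is_tensor(probs) else np.float32)
    ndim = probs.ndim
    voxel_axes = tuple(ax for ax in range(ndim) if ax != class_axis)
    n_classes = probs.shape[class_axis]
    inter = (probs * labels).sum(axis=voxel_axes)
    denom = (probs ** 2.0).sum(axis=voxel_axes) + (labels ** 2).sum(axis=voxel_axes) + eps
    dice = (2.0 * inter / denom).sum() * (1.0 / n_classes)
    return _as_float(1.0 - dice, _is_tensor(probs))


def focal_loss(probs, labels, alpha: float = 0.25, gamma: float = 2.0):
    """Binary focal loss, mean-reduced over voxels.

    ``probs`` is the predicted foreground probability per voxel; ``labels``
    the binary ground truth of identical shape.  Per voxel the term is
    ``-alpha_t (1 - p_t)^gamma log(p_t)`` with ``p_t = p`` where the label is
    1 and ``1 - p`` otherwise, ``alpha_t = alpha`` on foreground and
    ``1 - alpha`` on background.  Probabilities are clamped away from {0, 1}.
    """
    _check_shapes(probs, labels)
    terms = _focal_terms(probs, labels, alpha, gamma)
    return _as_float(terms.mean(), _is_tensor(probs))


def _focal_terms(probs, labels, alpha: float, gamma: float):
    """Per-voxel focal terms (shared by plain and region-weighted variants)."""
    y = np.asarray(labels, dtype=np.float64 if not _is_tensor(probs) else np.float32)
    p = probs.clip(*_P_CLIP) if _is_tensor(probs) else np.clip(probs, *_P_CLIP)
    p_t = p * y + (1.0 - p) * (1.0 - y)
    alpha_t = alpha * y + (1.0 - alpha) * (1.0 - y)
    if _is_tensor(probs):
        return alpha_t * ((1.0 - p_t) ** gamma) * (-(p_t.log()))
    return alpha_t * (1.0 - p_t) ** gamma * (-np.log(p_t))


def double_loss(probs, labels, config: LossConfig = LossConfig()):
    """Blend ``omega * dice + (1 - omega) * focal``.

    ``probs``/``labels`` are per-class grids as in :func:`dice_loss`
    (classes on axis 0, or axis 1 when batched 5D); the focal term uses the
    foreground (last) class channel.
    """
    class_axis = 1 if probs.ndim == 5 else 0
    d = dice_loss(probs, labels, config.eps, class_axis)
    fg = _take_class(probs, -1, class_axis)
    fg_labels = np.take(np.asarray(labels), -1, axis=class_axis)
    f = focal_loss(fg, fg_labels, config.alpha, config.gamma)
    return config.omega * d + (1.0 - config.omega) * f


def _take_class(probs, index: int, axis: int):
    if _is_tensor(probs):
        key = [slice(None)] * probs.ndim
        key[axis] = probs.shape[axis] + index if index < 0 else index
        return probs[tuple(key)]
    return np.take(probs, index, axis=axis)


def weighted_focal_loss(
    probs,
    labels,
    split: RegionSplit,
    alpha: float = 0.25,
    gamma: float = 2.0,
    lambda1: float = 0.5,
    lambda2: float = 1.5,
):
    """Region-weighted focal loss over a foreground difficulty split.

    The per-voxel weight map is ``lambda1`` on the easy core, ``lambda2`` on
    the hard remainder and 1 on background, applied to the focal terms before
    the mean reduction — so with ``lambda1 = lambda2 = 1`` this reduces
    exactly to :func:`focal_loss`, and background false positives always keep
    unit weight.
    """
    _check_shapes(probs, labels)
    lshape = tuple(np.shape(labels))
    if split.inside.shape not in (lshape, lshape[-3:]):
        raise ValueError("region split not aligned with labels")
    w = np.ones(split.inside.shape, dtype=np.float64)
    w[split.inside] = lambda1
    w[split.outside] = lambda2
    if _is_tensor(probs):
        w = w.astype(np.float32)
    terms = _focal_terms(probs, labels, alpha, gamma)
    return _as_float((terms * w).mean(), _is_tensor(probs))


def omega_double_loss(probs, labels, split: RegionSplit, config: LossConfig = LossConfig()):
    """Final training objective: ``omega * dice + (1 - omega) * weighted focal``."""
    class_axis = 1 if probs.ndim == 5 else 0
    d = dice_loss(probs, labels, config.eps, class_axis)
    fg = _take_class(probs, -1, class_axis)
    fg_labels = np.take(np.asarray(labels), -1, axis=class_axis)
    f = weighted_focal_loss(
        fg, fg_labels, split, config.alpha, config.gamma, config.lambda1, config.lambda2
    )
    return config.omega * d + (1.0 - config.omega) * f


def make_loss(name: str, config: LossConfig = LossConfig()):
    """Return ``loss(probs, labels, split)`` for a named objective."""
    name = name.lower()
    if name in ("dice",):
        return lambda p, g, s=None: dice_loss(p, g, config.eps, 1 if p.ndim == 5 else 0)
    if name in ("double", "doubleloss"):
        return lambda p, g, s=None: double_loss(p, g, config)
    if name in ("omega_double", "wdouble", "omegadoubleloss"):
        return lambda p, g, s: omega_double_loss(p, g, s, config)
    raise ValueError(f"unknown loss {name!r}")
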