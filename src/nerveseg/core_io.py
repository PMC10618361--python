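"""Volume and mask containers plus NIfTI-1 round-trip I/O.

Conventions used by every module in this package:

* in-memory arrays are indexed ``(z, y, x)``, 0-based;
* ``spacing`` is mm per voxel along ``(z, y, x)``;
* bounding boxes use half-open per-axis index ranges;
* volumes are reoriented to canonical anatomical (RAS) axis ordering on
  load, which removes per-scanner axis-permutation ambiguity.

Voxel centres live at ``origin + index * spacing`` (node convention); crops
and resamplings elsewhere in the package keep that bookkeeping consistent so
predictions can be mapped back to the native grid.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Sequence, Tuple

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "Mask",
    "BoundingBox",
    "ValidationError",
    "DimensionalityError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
]


class ValidationError(ValueError):
    """Raised when data violates a container invariant (NaNs, bad labels...)."""


class DimensionalityError(ValueError):
    """Raised when an image does not have exactly three scalar axes."""


def _check_spacing(spacing: Sequence[float]) -> Tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValidationError(f"spacing must have 3 components, got {len(spacing)}")
    if not all(np.isfinite(s) and s > 0 for s in spacing):
        raise ValidationError(f"spacing components must be positive and finite: {spacing}")
    return spacing


@dataclass
class Volume:
    """A 3D scalar grid with physical voxel spacing in mm.

    ``data`` is float32, axis order (z, y, x).
    """

    data: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"Volume data must have exactly 3 axes, got {self.data.ndim}"
            )
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        n_bad = int(np.size(self.data) - np.count_nonzero(np.isfinite(self.data)))
        if n_bad:
            raise ValidationError(f"Volume contains {n_bad} non-finite voxels")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume":
        return replace(self, data=np.asarray(data, dtype=np.float32))


@dataclass
class Mask:
    """A binary label grid aligned to a :class:`Volume`."""

    data: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise DimensionalityError(
                f"Mask data must have exactly 3 axes, got {data.ndim}"
            )
        vals = np.unique(data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValidationError(f"Mask values must be in {{0, 1}}, found {vals[:10]}")
        self.data = data.astype(np.uint8)
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Mask":
        return replace(self, data=data)


@dataclass(frozen=True)
class BoundingBox:
    """Half-open, 0-based per-axis index range ``[start, stop)``."""

    start: Tuple[int, int, int]
    stop: Tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.start) != 3 or len(self.stop) != 3:
            raise ValidationError("BoundingBox needs 3 axes")
        for a, b in zip(self.start, self.stop):
            if not (0 <= a < b):
                raise ValidationError(f"invalid box range [{a}, {b})")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(b - a for a, b in zip(self.start, self.stop))

    @property
    def slices(self) -> Tuple[slice, slice, slice]:
        return tuple(slice(a, b) for a, b in zip(self.start, self.stop))

    def padded(self, pad: int, grid_shape: Sequence[int]) -> "BoundingBox":
        """Expand by ``pad`` voxels per side, clipped to ``grid_shape``."""
        start = tuple(max(0, a - pad) for a in self.start)
        stop = tuple(min(n, b + pad) for b, n in zip(self.stop, grid_shape))
        return BoundingBox(start, stop)

    @staticmethod
    def of_foreground(mask_data: np.ndarray) -> "BoundingBox":
        idx = np.nonzero(mask_data)
        if idx[0].size == 0:
            raise ValidationError("cannot take bounding box of an empty mask")
        return BoundingBox(
            tuple(int(ax.min()) for ax in idx),
            tuple(int(ax.max()) + 1 for ax in idx),
        )


# ---------------------------------------------------------------------------
# NIfTI I/O.  nibabel stores data (x, y, z); we flip to (z, y, x) in memory.
# ---------------------------------------------------------------------------


def _load_canonical(path) -> tuple[np.ndarray, tuple, tuple]:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    if len(img.shape) != 3:
        raise DimensionalityError(
            f"expected a 3D scalar image, got shape {tuple(img.shape)}"
        )
    data_xyz = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    origin_xyz = img.affine[:3, 3]
    data = np.ascontiguousarray(data_xyz.transpose(2, 1, 0))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    origin = (float(origin_xyz[2]), float(origin_xyz[1]), float(origin_xyz[0]))
    return data, spacing, origin


def _affine_from(spacing_zyx, origin_zyx) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_zyx[2], spacing_zyx[1], spacing_zyx[0]
    aff[:3, 3] = (origin_zyx[2], origin_zyx[1], origin_zyx[0])
    return aff


def read_volume(path) -> Volume:
    """Read a 3D scalar NIfTI-1 image, reoriented to canonical axes.

    Raises :class:`DimensionalityError` for 4D images and
    :class:`ValidationError` when the file holds non-finite voxels.
    """
    data, spacing, origin = _load_canonical(path)
    data = data.astype(np.float32)
    n_bad = int(np.size(data) - np.count_nonzero(np.isfinite(data)))
    if n_bad:
        raise ValidationError(f"{path}: {n_bad} non-finite voxels")
    return Volume(data, spacing, origin)


def write_volume(volume: Volume, path) -> None:
    img = nib.Nifti1Image(
        np.ascontiguousarray(volume.data.transpose(2, 1, 0), dtype=np.float32),
        _affine_from(volume.spacing, volume.origin),
    )
    img.header.set_zooms((volume.spacing[2], volume.spacing[1], volume.spacing[0]))
    nib.save(img, str(path))


def read_mask(path) -> Mask:
    data, spacing, origin = _load_canonical(path)
    vals = np.unique(data)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValidationError(f"{path}: mask values outside {{0,1}}: {vals[:10]}")
    return Mask(data.astype(np.uint8), spacing, origin)


def write_mask(mask: Mask, path) -> None:
    vals = np.unique(mask.data)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValidationError(f"mask values outside {{0,1}}: {vals[:10]}")
    img = nib.Nifti1Image(
        np.ascontiguousarray(mask.data.transpose(2, 1, 0), dtype=np.uint8),
        _affine_from(mask.spacing, mask.origin),
    )
    img.header.set_zooms((mask.spacing[2], mask.spacing[1], mask.spacing[0]))
    nib.save(img, str(path))
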