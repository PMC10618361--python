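"""Preprocessing chain for anisotropic MR volumes.

Bias-field correction, connected-component ROI splitting (left/right nerve),
median-spacing resampling with nearest-neighbour interpolation, seeded random
patch cropping, and percentile intensity normalisation to [-1, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage

from .core_io import BoundingBox, Mask, Volume

__all__ = [
    "RoiInstance",
    "NormalizationParams",
    "correct_bias_field",
    "split_connected_rois",
    "median_spacing",
    "resample",
    "random_crop",
    "normalize_intensity",
]

_ORDINALS = ("first", "second", "third", "fourth", "fifth")


@dataclass
class RoiInstance:
    """One connected foreground component cropped to its (padded) box."""

    mask: Mask
    box: BoundingBox
    side_label: str
    n_voxels: int


@dataclass(frozen=True)
class NormalizationParams:
    """Percentile window and output range for intensity normalisation."""

    lower: float = 0.01
    upper: float = 0.99
    out_low: float = -1.0
    out_high: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower < self.upper <= 1.0):
            raise ValueError(f"need 0 <= lower < upper <= 1, got {self.lower}, {self.upper}")
        if self.out_low == self.out_high:
            raise ValueError("output range endpoints must be distinct")


# ---------------------------------------------------------------------------
# Bias-field correction
# ---------------------------------------------------------------------------


def _n4_correct(data: np.ndarray, spacing, shrink_factor: int, fit_levels: int) -> np.ndarray:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(data.astype(np.float32))
    img.SetSpacing((spacing[2], spacing[1], spacing[0]))
    mask = sitk.OtsuThreshold(img, 0, 1)
    small = img
    small_mask = mask
    if shrink_factor > 1:
        small = sitk.Shrink(img, [shrink_factor] * 3)
        small_mask = sitk.Shrink(mask, [shrink_factor] * 3)
    corrector = sitk.N4BiasFieldCorrectionImageFilter()
    corrector.SetMaximumNumberOfIterations([30] * max(1, fit_levels))
    corrector.Execute(small, small_mask)
    log_field = corrector.GetLogBiasFieldAsImage(img)
    field = np.exp(sitk.GetArrayFromImage(log_field)).astype(np.float64)
    field = np.clip(field, 1e-6, None)
    return (data / field).astype(np.float32)


def _polynomial_correct(data: np.ndarray, degree: int = 3) -> np.ndarray:
    """Fit a low-order polynomial to log-intensity of bright voxels and divide it out.

    A deliberately simple smooth-field estimator: the multiplicative field is
    modelled as exp(P(z, y, x)) with P a degree-``degree`` polynomial fitted by
    least squares over voxels above the median intensity.
    """
    shape = data.shape
    coords = [np.linspace(-1.0, 1.0, n) for n in shape]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    terms = []
    for i in range(degree + 1):
        for j in range(degree + 1 - i):
            for k in range(degree + 1 - i - j):
                terms.append((zz ** i) * (yy ** j) * (xx ** k))
    design_full = np.stack([t.ravel() for t in terms], axis=1)

    positive = np.clip(data, 1e-6, None).astype(np.float64)
    logv = np.log(positive).ravel()
    bright = positive.ravel() >= np.median(positive)
    coef, *_ = np.linalg.lstsq(design_full[bright], logv[bright], rcond=None)
    fit = design_full @ coef
    fit -= fit[bright].mean()  # unit-mean field over the fitted region
    field = np.exp(fit).reshape(shape)
    return (data / field).astype(np.float32)


def correct_bias_field(
    volume: Volume,
    shrink_factor: int = 4,
    fit_levels: int = 4,
    backend: str = "n4",
) -> Volume:
    """Remove smooth multiplicative intensity inhomogeneity.

    ``backend='n4'`` delegates to the standard N4 algorithm (SimpleITK);
    ``backend='polynomial'`` uses the built-in log-polynomial estimator.
    Intensities are shifted to be non-negative beforehand if needed; the
    correction never changes grid shape or spacing.
    """
    data = volume.data
    if not np.any(data):
        warnings.warn("constant-zero volume: nothing to correct", stacklevel=2)
        return volume.with_data(data.copy())
    shift = min(0.0, float(data.min()))
    work = data - shift
    if backend == "n4":
        try:
            corrected = _n4_correct(work, volume.spacing, shrink_factor, fit_levels)
        except ImportError:  # pragma: no cover - N4 backend present in normal installs
            corrected = _polynomial_correct(work)
    elif backend == "polynomial":
        corrected = _polynomial_correct(work)
    else:
        raise ValueError(f"unknown bias correction backend {backend!r}")
    return volume.with_data(corrected + shift)


# ---------------------------------------------------------------------------
# Connected-component ROI splitting
# ---------------------------------------------------------------------------


def split_connected_rois(
    mask: Mask, min_voxels: int = 1, pad_voxels: int = 0
) -> List[RoiInstance]:
    """Split a binary mask into per-component ROI instances.

    Components (26-connectivity) with fewer than ``min_voxels`` voxels are
    dropped.  Instances are ordered by descending size, ties broken by
    lexicographic bounding-box start, so the bilateral nerve case yields a
    deterministic (first, second) = (larger, smaller) pair.
    """
    labels, n = ndimage.label(mask.data, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        return []
    sizes = np.bincount(labels.ravel())[1:]
    entries = []
    for lab in range(1, n + 1):
        if sizes[lab - 1] < min_voxels:
            continue
        comp = labels == lab
        box = BoundingBox.of_foreground(comp)
        entries.append((int(sizes[lab - 1]), box, comp))
    entries.sort(key=lambda e: (-e[0], e[1].start))
    out: List[RoiInstance] = []
    for i, (size, box, comp) in enumerate(entries):
        pbox = box.padded(pad_voxels, mask.shape)
        sub = comp[pbox.slices].astype(np.uint8)
        origin = tuple(
            o + s * sp for o, s, sp in zip(mask.origin, pbox.start, mask.spacing)
        )
        label = _ORDINALS[i] if i < len(_ORDINALS) else f"component_{i + 1}"
        out.append(
            RoiInstance(
                mask=Mask(sub, mask.spacing, origin, mask.orientation),
                box=pbox,
                side_label=label,
                n_voxels=size,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def median_spacing(spacings: Sequence[Sequence[float]]) -> Tuple[float, float, float]:
    """Per-axis median of a set of voxel spacings (lower median for even counts),
    so the result is always an observed spacing value."""
    if len(spacings) == 0:
        raise ValueError("need at least one spacing")
    arr = np.asarray(spacings, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3 or np.any(arr <= 0):
        raise ValueError("spacings must be positive 3-vectors")
    arr = np.sort(arr, axis=0)
    return tuple(float(v) for v in arr[(arr.shape[0] - 1) // 2])


def _resample_indices(n_in: int, sp_in: float, sp_out: float) -> Tuple[int, np.ndarray]:
    n_out = max(1, int(np.floor(n_in * sp_in / sp_out + 0.5)))
    src = np.floor(np.arange(n_out) * (sp_out / sp_in) + 0.5).astype(np.intp)
    return n_out, np.clip(src, 0, n_in - 1)


def resample(
    obj: Union[Volume, Mask],
    target_spacing: Sequence[float],
    interpolation: str = "nearest",
) -> Union[Volume, Mask]:
    """Resample a volume or mask to ``target_spacing`` (mm) by nearest neighbour.

    Output shape per axis is ``round(n * spacing / target)`` (minimum 1).
    Resampling a volume and its mask with the same target keeps them aligned;
    masks stay binary.  Identity when the target equals the current spacing.
    """
    if interpolation != "nearest":
        raise ValueError(f"unsupported interpolation {interpolation!r}")
    target = tuple(float(t) for t in target_spacing)
    if len(target) != 3 or any(t <= 0 or not np.isfinite(t) for t in target):
        raise ValueError(f"target spacing must be positive: {target}")
    if target == tuple(obj.spacing):
        return obj.with_data(obj.data.copy())
    idx = []
    for n, sp, tsp in zip(obj.shape, obj.spacing, target):
        _, src = _resample_indices(n, sp, tsp)
        idx.append(src)
    data = obj.data[np.ix_(idx[0], idx[1], idx[2])]
    if isinstance(obj, Mask):
        return Mask(data, target, obj.origin, obj.orientation)
    return Volume(data, target, obj.origin, obj.orientation)


def resize_nearest(data: np.ndarray, out_shape: Sequence[int]) -> np.ndarray:
    """Nearest-neighbour resize to an exact target shape (helper for pasting
    fine-stage predictions back into native-grid boxes)."""
    idx = []
    for n_in, n_out in zip(data.shape, out_shape):
        src = np.floor((np.arange(n_out) + 0.5) * n_in / n_out).astype(np.intp)
        idx.append(np.clip(src, 0, n_in - 1))
    return data[np.ix_(*idx)]


# ---------------------------------------------------------------------------
# Cropping and normalisation
# ---------------------------------------------------------------------------


def _pad_to(data: np.ndarray, patch: Sequence[int], value) -> np.ndarray:
    pads = []
    for n, p in zip(data.shape, patch):
        short = max(0, p - n)
        pads.append((short // 2, short - short // 2))
    if any(a or b for a, b in pads):
        data = np.pad(data, pads, mode="constant", constant_values=value)
    return data


def random_crop(
    volume: Volume,
    mask: Mask,
    patch_size: Sequence[int],
    seed: int,
    foreground_prob: float = 0.5,
    pad_value: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Seeded random patch crop of an aligned (volume, mask) pair.

    With probability ``foreground_prob`` the patch is centred on a foreground
    voxel (when one exists).  Axes shorter than the patch are symmetrically
    padded first — the volume with ``pad_value`` (default: its minimum, i.e.
    background after [-1, 1] normalisation), the mask with 0.
    Returns plain arrays of exactly ``patch_size``.
    """
    patch = tuple(int(p) for p in patch_size)
    if len(patch) != 3 or any(p <= 0 for p in patch):
        raise ValueError(f"patch_size entries must be positive: {patch}")
    if volume.shape != mask.shape:
        raise ValueError(f"volume {volume.shape} and mask {mask.shape} misaligned")
    fill = float(volume.data.min()) if pad_value is None else float(pad_value)
    vol = _pad_to(volume.data, patch, fill)
    msk = _pad_to(mask.data, patch, 0)
    rng = np.random.default_rng(seed)
    fg = np.argwhere(msk > 0)
    if fg.size and rng.random() < foreground_prob:
        center = fg[rng.integers(len(fg))]
    else:
        center = np.array([rng.integers(n) for n in vol.shape])
    start = [
        int(np.clip(c - p // 2, 0, n - p)) for c, p, n in zip(center, patch, vol.shape)
    ]
    sl = tuple(slice(s, s + p) for s, p in zip(start, patch))
    return vol[sl].copy(), msk[sl].copy()


def normalize_intensity(
    volume: Volume,
    roi: Optional[Mask] = None,
    params: NormalizationParams = NormalizationParams(),
    mode: str = "affine",
) -> Volume:
    """Percentile-window intensity normalisation.

    Percentiles at ranks (``lower``, ``upper``) are computed over the ROI —
    when no mask is given, over voxels above the volume's 10th intensity
    percentile (an adaptive stand-in for a tissue ROI).  Intensities are
    clipped to that window and, in ``mode='affine'``, mapped affinely so the
    window endpoints land on (``out_low``, ``out_high``) = (-1, +1).
    ``mode='zscore'`` instead standardises the clipped values by the ROI mean
    and standard deviation.
    """
    data = volume.data.astype(np.float64)
    if roi is not None:
        if roi.shape != volume.shape:
            raise ValueError("ROI mask misaligned with volume")
        sel = data[roi.data > 0]
        if sel.size == 0:
            sel = data.ravel()
    else:
        thresh = np.percentile(data, 10.0)
        sel = data[data >= thresh]
        if sel.size == 0:
            sel = data.ravel()
    p_lo = np.percentile(sel, params.lower * 100.0)
    p_hi = np.percentile(sel, params.upper * 100.0)
    if p_hi <= p_lo:
        warnings.warn("degenerate intensity window; returning zeros", stacklevel=2)
        return volume.with_data(np.zeros_like(volume.data))
    clipped = np.clip(data, p_lo, p_hi)
    if mode == "affine":
        scale = (params.out_high - params.out_low) / (p_hi - p_lo)
        out = (clipped - p_lo) * scale + params.out_low
    elif mode == "zscore":
        mu = sel.mean()
        sd = sel.std()
        if sd == 0:
            warnings.warn("zero intensity variance; returning zeros", stacklevel=2)
            return volume.with_data(np.zeros_like(volume.data))
        out = (clipped - mu) / sd
    else:
        raise ValueError(f"unknown normalisation mode {mode!r}")
    return volume.with_data(out)
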