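"""Synthetic nerve phantoms.

Generates bright tubular "nerve" structures in textured, bias-corrupted
background volumes: a thick curved root tube ending in a ganglion bulge from
which three thinner distal branches diverge, optionally mirrored left/right.
This reproduces the statistical structure the segmentation method targets —
a thick, easy-to-segment core versus thin, under-segmentation-prone branches
on both sides of the head — so every pipeline stage is testable without
clinical data.

The phantoms make no claim of anatomical fidelity and do not simulate MR
physics; they provide controllable geometry, contrast, noise and a smooth
multiplicative bias field.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core_io import Mask, Volume, write_mask, write_volume

__all__ = ["PhantomSpec", "generate_phantom", "generate_phantom_parts", "generate_dataset"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and corruption parameters of one phantom.

    Radii and lengths are in voxels; intensities in arbitrary units.
    Branches must be strictly thinner than the root so the morphological
    easy/hard split is non-degenerate.
    """

    shape: Tuple[int, int, int] = (64, 96, 96)
    spacing: Tuple[float, float, float] = (0.5, 0.5, 0.5)
    root_radius_range: Tuple[float, float] = (3.0, 5.0)
    ganglion_extra_radius: float = 2.0
    branch_count: int = 3
    branch_radius_range: Tuple[float, float] = (1.2, 1.8)
    root_length_range: Tuple[int, int] = (24, 32)
    branch_length_range: Tuple[int, int] = (30, 42)
    tortuosity: float = 0.25
    fg_intensity: float = 200.0
    bg_intensity: float = 100.0
    noise_sigma: float = 8.0
    bias_amplitude: float = 0.3
    bilateral: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.branch_radius_range[1] >= self.root_radius_range[0]:
            raise ValueError("branches must be strictly thinner than the root")
        if min(self.root_radius_range[0], self.branch_radius_range[0]) < 1:
            raise ValueError("all radii must be >= 1 voxel")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.bias_amplitude < 0:
            raise ValueError("bias amplitude must be >= 0")


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    return v / n if n > 1e-9 else np.array([0.0, 1.0, 0.0])


def _walk(
    rng: np.random.Generator,
    start: np.ndarray,
    direction: np.ndarray,
    n_steps: int,
    lo: np.ndarray,
    hi: np.ndarray,
    tortuosity: float,
) -> np.ndarray:
    """Seeded 3D random-walk centreline with unit steps, clipped to a box."""
    pts = [np.clip(np.asarray(start, float), lo, hi)]
    d = _unit(np.asarray(direction, float))
    for _ in range(n_steps):
        d = _unit(d + rng.normal(0.0, tortuosity, size=3))
        pts.append(np.clip(pts[-1] + d, lo, hi))
    return np.asarray(pts)


def _rasterize(points: np.ndarray, radius: float, shape: Sequence[int]) -> np.ndarray:
    """Voxels within ``radius`` (Euclidean, voxel units) of the centreline."""
    seed_grid = np.zeros(shape, dtype=bool)
    idx = np.round(points).astype(int)
    idx = np.clip(idx, 0, np.asarray(shape) - 1)
    seed_grid[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    dist = ndimage.distance_transform_edt(~seed_grid)
    return dist <= radius


def _one_side(spec: PhantomSpec, rng: np.random.Generator) -> Dict[str, np.ndarray]:
    """Build root/ganglion/branch masks for the left half of the grid."""
    Z, Y, X = spec.shape
    root_r = rng.uniform(*spec.root_radius_range)
    gang_r = root_r + spec.ganglion_extra_radius
    margin = int(np.ceil(gang_r)) + 2
    mid = X // 2
    # keep every structure >=2 voxels clear of the midline so the mirrored
    # copy stays 26-disconnected from this side
    lo = np.array([margin, margin, margin], float)
    hi_root = np.array([Z - 1 - margin, Y - 1 - margin, mid - 2 - int(np.ceil(gang_r))], float)
    hi_branch = np.array(
        [Z - 1 - margin, Y - 1 - margin, mid - 2 - int(np.ceil(spec.branch_radius_range[1]))],
        float,
    )

    root_len = int(rng.integers(spec.root_length_range[0], spec.root_length_range[1] + 1))
    start = np.array(
        [Z / 2 + rng.uniform(-3, 3), lo[1] + 2, (lo[2] + hi_root[2]) / 2 + rng.uniform(-3, 3)]
    )
    root_pts = _walk(rng, start, np.array([0.0, 1.0, 0.1]), root_len, lo, hi_root, spec.tortuosity)
    root = _rasterize(root_pts, root_r, spec.shape)

    gang_center = root_pts[-1]
    ganglion = _rasterize(gang_center[None, :], gang_r, spec.shape)

    base_dirs = np.array(
        [[0.55, 0.75, -0.35], [-0.55, 0.75, 0.05], [0.1, 0.75, 0.55]], float
    )
    branch_list = []
    for b in range(spec.branch_count):
        d = base_dirs[b % len(base_dirs)] + rng.normal(0.0, 0.1, size=3)
        length = int(rng.integers(spec.branch_length_range[0], spec.branch_length_range[1] + 1))
        radius = rng.uniform(*spec.branch_radius_range)
        pts = _walk(rng, gang_center, d, length, lo, hi_branch, spec.tortuosity)
        branch_list.append(_rasterize(pts, radius, spec.shape))
    branches = np.zeros(spec.shape, dtype=bool)
    for bm in branch_list:
        branches |= bm
    coverage = np.sum(np.stack(branch_list), axis=0)

    return {
        "root": root,
        "ganglion": ganglion,
        "branches": branches,
        "_branch_overlap": coverage >= 2,
    }


def _bias_field(shape: Sequence[int], amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth strictly-positive field: exponentiated sum of 3 low-frequency
    cosine modes with random orientation and phase."""
    if amplitude == 0:
        return np.ones(shape)
    coords = np.meshgrid(
        *[np.linspace(0.0, 1.0, n) for n in shape], indexing="ij"
    )
    s = np.zeros(shape)
    for _ in range(3):
        k = rng.uniform(0.5, 1.5, size=3) * rng.choice([-1, 1], size=3)
        phase = rng.uniform(0, 2 * np.pi)
        s = s + np.cos(2 * np.pi * (k[0] * coords[0] + k[1] * coords[1] + k[2] * coords[2]) + phase)
    s = s / max(1e-9, np.abs(s).max())
    return np.exp(np.log1p(amplitude) * s)


def generate_phantom_parts(spec: PhantomSpec) -> Dict[str, np.ndarray]:
    """Like :func:`generate_phantom` but also exposes per-structure voxel sets.

    Returns a dict with the ``volume`` (:class:`Volume`), ``mask``
    (:class:`Mask`) and boolean arrays ``root``, ``ganglion``, ``branches``
    and ``distal_branches`` (branch voxels well clear of the thick core —
    the voxels an erosion of the core scale cannot retain).
    """
    rng = np.random.default_rng(spec.seed)
    parts = _one_side(spec, rng)
    if spec.bilateral:
        for key in list(parts):
            parts[key] = parts[key] | parts[key][:, :, ::-1]
    core = parts["root"] | parts["ganglion"]
    mask_arr = core | parts["branches"]

    # "distal" branch voxels: genuinely thin tube.  Excludes the neighbourhood
    # of the thick core and of any locally thick spot (branch crossings or a
    # tortuous branch folding onto itself), detected by the depth of the
    # foreground: a single thin tube is never deeper than its radius.
    parts.pop("_branch_overlap")
    r_max = spec.branch_radius_range[1]
    dist_to_core = ndimage.distance_transform_edt(~core)
    distal = parts["branches"] & ~core & (dist_to_core > r_max + 2.5)
    depth = ndimage.distance_transform_edt(mask_arr)
    thick = depth > r_max
    if thick.any():
        distal &= ndimage.distance_transform_edt(~thick) > r_max + 2.5
    parts["distal_branches"] = distal

    smooth_fg = ndimage.gaussian_filter(mask_arr.astype(np.float64), sigma=0.7)
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, spec.shape), sigma=2.0)
    texture *= 0.1 * (spec.fg_intensity - spec.bg_intensity) / max(1e-9, texture.std())
    base = spec.bg_intensity + (spec.fg_intensity - spec.bg_intensity) * smooth_fg
    base = base + texture * (1.0 - smooth_fg)
    field = _bias_field(spec.shape, spec.bias_amplitude, rng)
    noisy = base * field + rng.normal(0.0, spec.noise_sigma, spec.shape)

    parts["volume"] = Volume(noisy.astype(np.float32), spec.spacing)
    parts["mask"] = Mask(mask_arr.astype(np.uint8), spec.spacing)
    parts["prenoise"] = base
    return parts


def generate_phantom(spec: PhantomSpec) -> Tuple[Volume, Mask]:
    """Generate one seeded phantom (volume, mask) pair."""
    parts = generate_phantom_parts(spec)
    return parts["volume"], parts["mask"]


def _draw_spec(base: PhantomSpec, ranges: Optional[dict], rng: np.random.Generator, seed: int) -> PhantomSpec:
    updates = {"seed": seed}
    for key, rng_spec in (ranges or {}).items():
        if isinstance(rng_spec, list):
            updates[key] = rng_spec[rng.integers(len(rng_spec))]
        else:
            lo, hi = rng_spec
            if isinstance(lo, int) and isinstance(hi, int):
                updates[key] = int(rng.integers(lo, hi + 1))
            else:
                updates[key] = float(rng.uniform(lo, hi))
    return replace(base, **updates)


def generate_dataset(
    n: int,
    base_spec: PhantomSpec = PhantomSpec(),
    ranges: Optional[dict] = None,
    seed: int = 0,
    out_dir: Optional[Path] = None,
    test_fraction: float = 0.0,
) -> Tuple[List[Tuple[Volume, Mask]], List[dict]]:
    """Generate ``n`` phantoms with per-case spec fields drawn from ``ranges``.

    ``ranges`` maps PhantomSpec field names to either ``(low, high)`` draws or
    a list of discrete options (e.g. candidate spacings).  Returns the cases
    plus a manifest (one record per case: resolved spec, seed, train/test
    split by index — the last ``round(n * test_fraction)`` cases are test).
    Replaying a manifest record through :class:`PhantomSpec` regenerates the
    identical volume.  When ``out_dir`` is given, NIfTI pairs and
    ``manifest.json`` are written there.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    n_test = int(round(n * test_fraction))
    cases: List[Tuple[Volume, Mask]] = []
    manifest: List[dict] = []
    for i in range(n):
        case_seed = int(rng.integers(0, 2**31 - 1))
        spec = _draw_spec(base_spec, ranges, rng, case_seed)
        vol, mask = generate_phantom(spec)
        cases.append((vol, mask))
        rec = {"index": i, "split": "test" if i >= n - n_test else "train", "spec": asdict(spec)}
        manifest.append(rec)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec, (vol, mask) in zip(manifest, cases):
            stem = f"case_{rec['index']:03d}"
            write_volume(vol, out_dir / f"{stem}_image.nii.gz")
            write_mask(mask, out_dir / f"{stem}_mask.nii.gz")
            rec["image"] = f"{stem}_image.nii.gz"
            rec["mask"] = f"{stem}_mask.nii.gz"
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return cases, manifest
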