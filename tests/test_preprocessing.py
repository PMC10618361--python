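"""Preprocessing chain: bias correction, ROI splitting, resampling, cropping,
intensity normalisation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import flood_fill_label
from nerveseg.core_io import Mask, Volume
from nerveseg.preprocessing import (
    correct_bias_field,
    median_spacing,
    normalize_intensity,
    random_crop,
    resample,
    split_connected_rois,
)


# ---------------------------------------------------------------------------
# median spacing
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "spacings,expected",
    [
        ([(0.5, 0.5, 0.5)], (0.5, 0.5, 0.5)),
        ([(0.5, 0.5, 1.0), (0.5, 0.5, 0.5), (1.0, 1.0, 1.0)], (0.5, 0.5, 1.0)),
    ],
)
def test_median_spacing_examples(spacings, expected):
    assert median_spacing(spacings) == expected


def test_median_spacing_even_count_takes_lower_median(rng):
    spacings = [tuple(v) for v in rng.uniform(0.3, 2.0, (4, 3))]
    result = median_spacing(spacings)
    for axis in range(3):
        assert result[axis] == sorted(s[axis] for s in spacings)[1]


def test_median_spacing_empty_rejected():
    with pytest.raises(ValueError):
        median_spacing([])


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def test_resample_identity_when_spacing_matches(rng):
    vol = Volume(rng.normal(0, 1, (10, 12, 14)).astype(np.float32), (0.5, 0.6, 0.7))
    out = resample(vol, (0.5, 0.6, 0.7))
    np.testing.assert_array_equal(out.data, vol.data)
    assert out.shape == vol.shape


def test_resample_halves_grid_at_double_spacing():
    vol = Volume(np.zeros((64, 64, 64), np.float32), (0.5, 0.5, 0.5))
    out = resample(vol, (1.0, 1.0, 1.0))
    assert out.shape == (32, 32, 32)
    assert out.spacing == (1.0, 1.0, 1.0)


def test_resample_keeps_masks_binary_and_aligned(rng):
    data = (rng.random((20, 24, 28)) > 0.6).astype(np.uint8)
    mask = Mask(data, (0.5, 0.5, 0.5))
    vol = Volume(data * 100.0, (0.5, 0.5, 0.5))
    rm = resample(mask, (0.8, 0.8, 0.8))
    rv = resample(vol, (0.8, 0.8, 0.8))
    assert set(np.unique(rm.data)) <= {0, 1}
    assert rm.shape == rv.shape
    np.testing.assert_array_equal(rm.data * 100.0, rv.data)


def test_resample_rejects_non_positive_spacing():
    vol = Volume(np.zeros((4, 4, 4), np.float32), (1, 1, 1))
    with pytest.raises(ValueError):
        resample(vol, (0.0, 1.0, 1.0))


# ---------------------------------------------------------------------------
# connected-component ROI splitting
# ---------------------------------------------------------------------------


def _place_cube(grid, start, size=3):
    sl = tuple(slice(s, s + size) for s in start)
    grid[sl] = 1


def test_two_cubes_yield_two_equal_instances():
    grid = np.zeros((16, 16, 16), np.uint8)
    _place_cube(grid, (1, 1, 1))
    _place_cube(grid, (10, 10, 10))
    rois = split_connected_rois(Mask(grid, (1, 1, 1)))
    assert len(rois) == 2
    assert all(r.n_voxels == 27 for r in rois)
    assert rois[0].side_label == "first" and rois[1].side_label == "second"


def test_single_blob_round_trips_through_instance():
    grid = np.zeros((10, 10, 10), np.uint8)
    _place_cube(grid, (3, 3, 3), 4)
    rois = split_connected_rois(Mask(grid, (1, 1, 1)))
    assert len(rois) == 1
    rebuilt = np.zeros_like(grid)
    rebuilt[rois[0].box.slices] = rois[0].mask.data
    np.testing.assert_array_equal(rebuilt, grid)


def test_min_voxels_drops_small_component_vs_flood_fill():
    grid = np.zeros((16, 16, 16), np.uint8)
    grid[2:6, 2:7, 2:7] = 1  # 100 voxels
    grid[12, 12, 12:15] = 1  # 3 voxels
    labels, n = flood_fill_label(grid)
    sizes = sorted(np.bincount(labels.ravel())[1:])
    assert (n, sizes) == (2, [3, 100])
    rois = split_connected_rois(Mask(grid, (1, 1, 1)), min_voxels=10)
    assert len(rois) == 1 and rois[0].n_voxels == 100


def test_empty_mask_yields_empty_list():
    assert split_connected_rois(Mask(np.zeros((4, 4, 4), np.uint8), (1, 1, 1))) == []


def test_split_agrees_with_flood_fill_oracle_on_random_masks(rng):
    for _ in range(30):
        grid = (rng.random((16, 16, 16)) > 0.85).astype(np.uint8)
        labels, n = flood_fill_label(grid)
        rois = split_connected_rois(Mask(grid, (1, 1, 1)))
        assert len(rois) == n
        oracle_sizes = sorted(np.bincount(labels.ravel())[1:], reverse=True)
        assert [r.n_voxels for r in rois] == [int(s) for s in oracle_sizes]
        rebuilt = np.zeros_like(grid)
        for r in rois:
            rebuilt[r.box.slices] |= r.mask.data
        np.testing.assert_array_equal(rebuilt, grid)


# ---------------------------------------------------------------------------
# random cropping
# ---------------------------------------------------------------------------


def _pair(rng, shape=(12, 14, 16)):
    vol = Volume(rng.normal(0, 1, shape).astype(np.float32), (1, 1, 1))
    mask = Mask((rng.random(shape) > 0.9).astype(np.uint8), (1, 1, 1))
    return vol, mask


def test_crop_whole_volume_is_identity(rng):
    vol, mask = _pair(rng)
    vp, mp = random_crop(vol, mask, vol.shape, seed=0)
    np.testing.assert_array_equal(vp, vol.data)
    np.testing.assert_array_equal(mp, mask.data)


def test_crop_seeded_determinism(rng):
    vol, mask = _pair(rng)
    a = random_crop(vol, mask, (6, 6, 6), seed=42)
    b = random_crop(vol, mask, (6, 6, 6), seed=42)
    np.testing.assert_array_equal(a[0], b[0])
    np.testing.assert_array_equal(a[1], b[1])


def test_foreground_guarantee_with_single_voxel(rng):
    shape = (12, 12, 12)
    vol = Volume(rng.normal(0, 1, shape).astype(np.float32), (1, 1, 1))
    grid = np.zeros(shape, np.uint8)
    grid[3, 8, 5] = 1
    mask = Mask(grid, (1, 1, 1))
    for seed in range(50):
        _, mp = random_crop(vol, mask, (5, 5, 5), seed=seed, foreground_prob=1.0)
        assert mp.sum() == 1


def test_short_axes_are_padded_to_patch(rng):
    vol, mask = _pair(rng, (4, 14, 16))
    vp, mp = random_crop(vol, mask, (8, 8, 8), seed=1)
    assert vp.shape == (8, 8, 8) and mp.shape == (8, 8, 8)
    assert set(np.unique(mp)) <= {0, 1}


def test_bad_patch_size_rejected(rng):
    vol, mask = _pair(rng)
    with pytest.raises(ValueError):
        random_crop(vol, mask, (0, 5, 5), seed=0)


# ---------------------------------------------------------------------------
# intensity normalisation
# ---------------------------------------------------------------------------


def test_constant_volume_normalises_to_zeros():
    vol = Volume(np.full((6, 6, 6), 7.0, np.float32), (1, 1, 1))
    with pytest.warns(UserWarning):
        out = normalize_intensity(vol)
    assert not out.data.any()


def test_linear_ramp_maps_to_symmetric_unit_range():
    data = np.linspace(0.0, 1000.0, 16**3, dtype=np.float32).reshape(16, 16, 16)
    vol = Volume(data, (1, 1, 1))
    roi = Mask(np.ones_like(data, np.uint8), (1, 1, 1))
    out = normalize_intensity(vol, roi=roi)
    assert out.data.min() == pytest.approx(-1.0, abs=1e-6)
    assert out.data.max() == pytest.approx(1.0, abs=1e-6)
    # median of the ramp maps near the centre of the output range
    mid = np.median(out.data)
    assert abs(mid) < 0.01
    assert np.all(out.data >= -1.0) and np.all(out.data <= 1.0)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    scale=st.floats(0.1, 50.0),
    offset=st.floats(-100.0, 100.0),
)
def test_normalisation_invariant_to_positive_affine_input_transform(scale, offset):
    rng = np.random.default_rng(7)
    data = rng.normal(50.0, 10.0, (10, 10, 10))
    base = normalize_intensity(Volume(data.astype(np.float32), (1, 1, 1)))
    moved = normalize_intensity(
        Volume((scale * data + offset).astype(np.float32), (1, 1, 1))
    )
    np.testing.assert_allclose(base.data, moved.data, atol=2e-5)


def test_zscore_mode_standardises_roi():
    rng = np.random.default_rng(3)
    data = rng.normal(10.0, 2.0, (12, 12, 12)).astype(np.float32)
    roi = Mask(np.ones_like(data, np.uint8), (1, 1, 1))
    out = normalize_intensity(Volume(data, (1, 1, 1)), roi=roi, mode="zscore")
    assert abs(out.data.mean()) < 0.1
    assert 0.7 < out.data.std() < 1.1


# ---------------------------------------------------------------------------
# bias-field correction
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("backend", ["n4", "polynomial"])
def test_bias_free_volume_barely_changed(backend, rng):
    data = 100.0 + rng.normal(0.0, 1.0, (24, 24, 24)).astype(np.float32)
    vol = Volume(data, (1, 1, 1))
    out = correct_bias_field(vol, backend=backend)
    rel = np.abs(out.data - data) / 100.0
    assert out.shape == vol.shape and out.spacing == vol.spacing
    assert np.median(rel) < 0.05


@pytest.mark.parametrize("backend", ["n4", "polynomial"])
def test_known_quadratic_field_reduces_foreground_cv(backend):
    rng = np.random.default_rng(5)
    shape = (24, 24, 24)
    coords = np.meshgrid(*[np.linspace(-1, 1, n) for n in shape], indexing="ij")
    field = 1.0 + 0.3 * (coords[0] ** 2 - coords[1] * coords[2])
    clean = np.full(shape, 100.0) + rng.normal(0, 2.0, shape)
    vol = Volume((clean * field).astype(np.float32), (1, 1, 1))
    out = correct_bias_field(vol, backend=backend)
    cv_before = vol.data.std() / vol.data.mean()
    cv_after = out.data.std() / out.data.mean()
    assert cv_after < cv_before


@pytest.mark.parametrize("backend", ["n4", "polynomial"])
def test_correction_approximately_idempotent(backend):
    rng = np.random.default_rng(9)
    shape = (32, 32, 32)
    coords = np.meshgrid(*[np.linspace(-1, 1, n) for n in shape], indexing="ij")
    field = np.exp(0.25 * coords[0] + 0.2 * coords[1] ** 2)
    vol = Volume((100.0 * field + rng.normal(0, 1, shape)).astype(np.float32), (1, 1, 1))
    # no pyramid shrinking: the grid is already small
    once = correct_bias_field(vol, shrink_factor=1, backend=backend)
    twice = correct_bias_field(once, shrink_factor=1, backend=backend)
    rms = np.sqrt(np.mean((twice.data - once.data) ** 2)) / np.sqrt(np.mean(once.data**2))
    assert rms < 0.02


def test_zero_volume_is_noop_with_warning():
    vol = Volume(np.zeros((6, 6, 6), np.float32), (1, 1, 1))
    with pytest.warns(UserWarning):
        out = correct_bias_field(vol)
    assert not out.data.any()
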