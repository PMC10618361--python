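"""Loss functions against per-voxel oracles, analytic reductions and the
morphological difficulty split."""

import numpy as np
import pytest

from conftest import (
    brute_opening,
    dice_loss_oracle,
    focal_loss_oracle,
    focal_terms_oracle,
)
import nerveseg.nn as nn
from nerveseg.losses import (
    LossConfig,
    RegionSplit,
    dice_loss,
    double_loss,
    focal_loss,
    omega_double_loss,
    split_difficulty_regions,
    weighted_focal_loss,
)


def _random_instance(seed, shape=(8, 8, 8)):
    rng = np.random.default_rng(seed)
    p_fg = rng.uniform(0.02, 0.98, shape)
    probs = np.stack([1 - p_fg, p_fg])
    labels_fg = (rng.random(shape) > 0.8).astype(float)
    labels = np.stack([1 - labels_fg, labels_fg])
    return probs, labels


# ---------------------------------------------------------------------------
# worked examples
# ---------------------------------------------------------------------------


def test_dice_worked_example_single_class():
    g = np.array([[1.0, 1, 0, 0]])
    p = np.array([[0.8, 0.6, 0.2, 0.4]])
    assert dice_loss(p, g, eps=0.0) == pytest.approx(0.125, abs=1e-12)


def test_dice_perfect_and_complete_miss():
    _, labels = _random_instance(0)
    assert dice_loss(labels.astype(float), labels) == pytest.approx(0.0, abs=1e-6)
    assert dice_loss(1.0 - labels, labels) == pytest.approx(1.0, abs=1e-6)


def test_focal_single_voxel_closed_form():
    value = focal_loss(np.array([0.9]), np.array([1.0]), alpha=0.25, gamma=2.0)
    assert value == pytest.approx(0.25 * 0.1**2 * -np.log(0.9), rel=1e-9)
    assert value == pytest.approx(2.634e-4, rel=1e-3)


def test_confident_correct_prediction_has_negligible_loss():
    p = np.full((5, 5, 5), 1.0 - 1e-7)
    y = np.ones((5, 5, 5))
    assert focal_loss(p, y) < 1e-6


def test_dice_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        dice_loss(np.zeros((2, 4)), np.zeros((2, 5)))


# ---------------------------------------------------------------------------
# oracle equivalence
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("seed", range(10))
def test_losses_match_per_voxel_oracles(seed):
    probs, labels = _random_instance(seed)
    assert dice_loss(probs, labels) == pytest.approx(
        dice_loss_oracle(probs, labels), abs=1e-6
    )
    assert focal_loss(probs[1], labels[1]) == pytest.approx(
        focal_loss_oracle(probs[1], labels[1]), abs=1e-6
    )


def test_composite_losses_compose_their_oracles(rng):
    for seed in range(10):
        probs, labels = _random_instance(seed)
        split = split_difficulty_regions(labels[1].astype(np.uint8), 1)
        cfg = LossConfig(omega=0.3, lambda1=0.5, lambda2=2.0)
        d = dice_loss_oracle(probs, labels)
        terms = focal_terms_oracle(probs[1], labels[1], cfg.alpha, cfg.gamma)
        w = np.ones(labels[1].size)
        w[split.inside.ravel()] = cfg.lambda1
        w[split.outside.ravel()] = cfg.lambda2
        wf = float((terms * w).mean())
        expected = cfg.omega * d + (1 - cfg.omega) * wf
        assert omega_double_loss(probs, labels, split, cfg) == pytest.approx(expected, abs=1e-6)


# ---------------------------------------------------------------------------
# analytic reductions
# ---------------------------------------------------------------------------


def test_omega_extremes_select_single_terms():
    probs, labels = _random_instance(3)
    cfg1 = LossConfig(omega=1.0)
    cfg0 = LossConfig(omega=0.0)
    assert double_loss(probs, labels, cfg1) == pytest.approx(
        dice_loss(probs, labels, cfg1.eps), abs=1e-12
    )
    assert double_loss(probs, labels, cfg0) == pytest.approx(
        focal_loss(probs[1], labels[1], cfg0.alpha, cfg0.gamma), abs=1e-12
    )


def test_unit_lambdas_collapse_weighted_to_plain():
    probs, labels = _random_instance(4)
    split = split_difficulty_regions(labels[1].astype(np.uint8), 1)
    cfg = LossConfig(lambda1=1.0, lambda2=1.0)
    assert weighted_focal_loss(
        probs[1], labels[1], split, cfg.alpha, cfg.gamma, 1.0, 1.0
    ) == pytest.approx(focal_loss(probs[1], labels[1], cfg.alpha, cfg.gamma), abs=1e-12)
    assert omega_double_loss(probs, labels, split, cfg) == pytest.approx(
        double_loss(probs, labels, cfg), abs=1e-12
    )


def test_gamma_zero_alpha_half_is_half_cross_entropy():
    rng = np.random.default_rng(8)
    p = rng.uniform(0.05, 0.95, (6, 6, 6))
    y = (rng.random((6, 6, 6)) > 0.5).astype(float)
    bce = float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())
    assert focal_loss(p, y, alpha=0.5, gamma=0.0) == pytest.approx(0.5 * bce, abs=1e-9)


def test_perfect_prediction_zero_weighted_loss_any_lambda():
    _, labels = _random_instance(5)
    split = split_difficulty_regions(labels[1].astype(np.uint8), 1)
    val = weighted_focal_loss(labels[1], labels[1], split, 0.25, 2.0, 0.1, 9.0)
    assert val < 1e-6


def test_two_voxel_weighted_sum_hand_computed():
    probs = np.array([[[0.6, 0.6, 0.9, 0.9]]])  # (1,1,4)
    labels = np.array([[[1.0, 1.0, 0.0, 0.0]]])
    inside = np.array([[[True, False, False, False]]])
    outside = np.array([[[False, True, False, False]]])
    split = RegionSplit(inside, outside, inside | outside)
    f = 0.25 * 0.4**2 * -np.log(0.6)  # focal term at each foreground voxel
    b = 0.75 * 0.9**2 * -np.log(0.1)  # background terms (p=0.9, y=0)
    expected = (1.0 * f + 3.0 * f + 2 * b) / 4.0
    got = weighted_focal_loss(probs, labels, split, 0.25, 2.0, 1.0, 3.0)
    assert got == pytest.approx(expected, rel=1e-9)


# ---------------------------------------------------------------------------
# difficulty split
# ---------------------------------------------------------------------------


def test_thin_tube_is_all_outside():
    tube = np.zeros((12, 12, 12), np.uint8)
    tube[6, 2:10, 6] = 1
    split = split_difficulty_regions(tube, 2)
    assert not split.inside.any()
    np.testing.assert_array_equal(split.outside, tube.astype(bool))


def test_solid_cube_split_with_cross_element_matches_brute_force():
    """Erosion of a 9^3 cube by the 6-connected cross leaves the 7^3 interior;
    the reopening covers everything except the corner/edge shell, which the
    split assigns to the thin region."""
    from conftest import brute_dilation, brute_erosion

    cube = np.zeros((13, 13, 13), np.uint8)
    cube[2:11, 2:11, 2:11] = 1
    cross = np.zeros((3, 3, 3), bool)
    cross[1, 1, :] = cross[1, :, 1] = cross[:, 1, 1] = True
    split = split_difficulty_regions(cube, 1, structure=cross)
    cross_offs = [(0, 0, 0), (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    eroded = brute_erosion(cube, cross_offs)
    assert eroded.sum() == 7**3
    opened = brute_dilation(eroded, cross_offs)
    np.testing.assert_array_equal(split.inside, opened)
    np.testing.assert_array_equal(split.outside, cube.astype(bool) & ~opened)
    # the interior bulk is retained (7^3 + six 7^2 faces = 637 of 729);
    # only the corner/edge shell is "thin"
    assert split.inside.sum() == 7**3 + 6 * 7**2


def test_split_partition_invariants_and_brute_force_oracle(rng):
    for _ in range(25):
        mask = (rng.random((16, 16, 16)) > 0.7).astype(np.uint8)
        split = split_difficulty_regions(mask, 2)
        assert not (split.inside & split.outside).any()
        np.testing.assert_array_equal(split.inside | split.outside, mask.astype(bool))
        np.testing.assert_array_equal(split.inside, brute_opening(mask, 2))


def test_empty_mask_yields_empty_regions():
    split = split_difficulty_regions(np.zeros((5, 5, 5), np.uint8), 2)
    assert not split.inside.any() and not split.outside.any()


def test_phantom_distal_branches_fall_outside_core(default_phantom_parts):
    parts = default_phantom_parts
    split = split_difficulty_regions(parts["mask"].data, 2)
    distal = parts["distal_branches"]
    assert (split.outside & distal).sum() == distal.sum()
    assert (split.inside & parts["root"]).any()


# ---------------------------------------------------------------------------
# structural properties
# ---------------------------------------------------------------------------


def test_dice_symmetric_under_voxel_permutation(rng):
    probs, labels = _random_instance(9)
    perm = rng.permutation(probs[0].size)
    probs_p = probs.reshape(2, -1)[:, perm]
    labels_p = labels.reshape(2, -1)[:, perm]
    assert dice_loss(probs, labels) == pytest.approx(dice_loss(probs_p, labels_p), rel=1e-12)


def test_loss_increases_with_lambda2_when_outside_error_positive():
    probs, labels = _random_instance(10)
    split = split_difficulty_regions(labels[1].astype(np.uint8), 1)
    assert split.outside.any()
    vals = [
        omega_double_loss(probs, labels, split, LossConfig(lambda2=l2))
        for l2 in (0.5, 1.0, 2.0, 4.0)
    ]
    assert all(b > a for a, b in zip(vals, vals[1:]))


def test_losses_nonnegative_and_autodiff_matches_finite_difference():
    probs, labels = _random_instance(11, shape=(4, 4, 4))
    split = split_difficulty_regions(labels[1].astype(np.uint8), 1)
    cfg = LossConfig()
    t = nn.Parameter(probs.astype("f4"))
    loss = omega_double_loss(t, labels.astype("f4"), split, cfg)
    assert float(loss.data) >= 0.0
    loss.backward()
    rng = np.random.default_rng(0)
    for _ in range(5):
        idx = tuple(rng.integers(0, s) for s in t.shape)
        orig = t.data[idx]
        eps = 1e-3
        t.data[idx] = orig + eps
        f1 = float(omega_double_loss(t, labels.astype("f4"), split, cfg).data)
        t.data[idx] = orig - eps
        f0 = float(omega_double_loss(t, labels.astype("f4"), split, cfg).data)
        t.data[idx] = orig
        numeric = (f1 - f0) / (2 * eps)
        assert numeric == pytest.approx(t.grad[idx], abs=2e-3 + 1e-3 * abs(numeric))
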