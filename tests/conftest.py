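"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the code paths they check: connected
components via breadth-first flood fill, morphology via explicit structuring
-element shifts, losses via per-voxel Python loops.
"""

from __future__ import annotations

import numpy as np
import pytest

from nerveseg.phantom import PhantomSpec, generate_phantom_parts


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def flood_fill_label(mask: np.ndarray):
    """26-connectivity component labelling by breadth-first flood fill."""
    from collections import deque

    mask = mask.astype(bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    current = 0
    for seed in zip(*np.nonzero(mask)):
        if labels[seed]:
            continue
        current += 1
        queue = deque([seed])
        labels[seed] = current
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in offsets:
                n = (z + dz, y + dy, x + dx)
                if all(0 <= c < s for c, s in zip(n, mask.shape)) and mask[n] and not labels[n]:
                    labels[n] = current
                    queue.append(n)
    return labels, current


def ball_offsets(radius: int):
    r = int(radius)
    return [
        (dz, dy, dx)
        for dz in range(-r, r + 1)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if dz * dz + dy * dy + dx * dx <= r * r
    ]


def _shift(mask: np.ndarray, off, fill: bool) -> np.ndarray:
    out = np.full_like(mask, fill)
    src = tuple(
        slice(max(0, -o), mask.shape[i] - max(0, o)) for i, o in enumerate(off)
    )
    dst = tuple(
        slice(max(0, o), mask.shape[i] - max(0, -o)) for i, o in enumerate(off)
    )
    out[dst] = mask[src]
    return out


def brute_erosion(mask: np.ndarray, offsets) -> np.ndarray:
    """Erosion as the AND of the mask shifted by every structuring offset."""
    mask = mask.astype(bool)
    out = np.ones_like(mask)
    for off in offsets:
        out &= _shift(mask, tuple(-o for o in off), False)
    return out


def brute_dilation(mask: np.ndarray, offsets) -> np.ndarray:
    mask = mask.astype(bool)
    out = np.zeros_like(mask)
    for off in offsets:
        out |= _shift(mask, off, False)
    return out


def brute_opening(mask: np.ndarray, radius: int) -> np.ndarray:
    offs = ball_offsets(radius)
    return brute_dilation(brute_erosion(mask, offs), offs)


def dice_loss_oracle(probs: np.ndarray, labels: np.ndarray, eps: float = 1e-5) -> float:
    """Per-voxel loop evaluation of the multi-class soft dice loss."""
    n_classes = probs.shape[0]
    total = 0.0
    for c in range(n_classes):
        inter = pp = gg = 0.0
        for p, g in zip(probs[c].ravel(), labels[c].ravel()):
            inter += p * g
            pp += p * p
            gg += g * g
        total += 2.0 * inter / (pp + gg + eps)
    return 1.0 - total / n_classes


def focal_terms_oracle(probs, labels, alpha, gamma):
    terms = []
    for p, y in zip(np.ravel(probs), np.ravel(labels)):
        p = min(max(p, 1e-7), 1 - 1e-7)
        p_t = p if y == 1 else 1 - p
        a_t = alpha if y == 1 else 1 - alpha
        terms.append(-a_t * (1 - p_t) ** gamma * np.log(p_t))
    return np.array(terms)


def focal_loss_oracle(probs, labels, alpha=0.25, gamma=2.0) -> float:
    return float(focal_terms_oracle(probs, labels, alpha, gamma).mean())


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def default_phantom_parts():
    return generate_phantom_parts(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def small_phantom_parts():
    return generate_phantom_parts(PhantomSpec(shape=(48, 64, 64), seed=2))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
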