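"""Shared oracles and fixtures for the fibermesi test suite.

The oracles here are deliberately naive (explicit loops, direct formulas)
so they are independent of the vectorized implementations they check.
"""
from __future__ import annotations

import math

import numpy as np
import pytest

from fibermesi.bundle import FiberMap


def contrast_oracle(image: np.ndarray, window: int) -> np.ndarray:
    """Brute-force sliding-window contrast: per-pixel double loop.

    Returns a map with NaN outside the valid interior, sample std (N-1)
    over mean inside, matching the documented convention.
    """
    img = np.asarray(image, dtype=float)
    h = window // 2
    out = np.full(img.shape, np.nan)
    for r in range(h, img.shape[0] - h):
        for c in range(h, img.shape[1] - h):
            patch = img[r - h : r + h + 1, c - h : c + h + 1].ravel()
            m = patch.mean()
            if m == 0:
                continue
            out[r, c] = patch.std(ddof=1) / m
    return out


def hex_enumeration_oracle(n_rings: int) -> int:
    """Count axial-coordinate lattice sites with ring index in [1, n_rings]."""
    count = 0
    span = n_rings + 1
    for q in range(-span, span + 1):
        for r in range(-span, span + 1):
            ring = max(abs(q), abs(r), abs(q + r))
            if 1 <= ring <= n_rings:
                count += 1
    return count


def decay_oracle(y: float) -> float:
    """(e^-y - 1 + y) / y^2 via expm1 (stable for tiny y)."""
    return (math.expm1(-y) + y) / (y * y)


def mesi_oracle(T, tau_c, beta, rho, nu):
    x = T / tau_c
    return (
        beta * rho**2 * decay_oracle(2 * x) * 2
        + 4 * beta * rho * (1 - rho) * decay_oracle(x)
        + nu
    )


def make_fiber_map(centers, radius: float, shape) -> FiberMap:
    """Small FiberMap with disc memberships assigned to the nearest center."""
    from scipy.spatial import cKDTree

    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    rr, cc = np.indices(shape)
    pixels = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    d, nearest = cKDTree(centers).query(pixels)
    labels = np.where(d <= radius, nearest + 1, 0).reshape(shape).astype(np.int32)
    return FiberMap(
        centers=centers,
        radii=np.full(len(centers), float(radius)),
        labels=labels,
        image_shape=tuple(shape),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240615)
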