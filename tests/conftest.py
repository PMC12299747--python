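"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def calipers_min_area(points: np.ndarray, step_deg: float = 0.1, inflation: float = 0.0) -> float:
    """Brute-force minimum-area enclosing rectangle by angle sweep.

    Rotates the point cloud through [0, 90) degrees in ``step_deg``
    increments and takes the smallest axis-aligned bounding-box area,
    each box side grown by ``inflation`` (the half-pixel disk dilation
    adds exactly 1 px per side at every angle).  Independent of the
    hull-based implementation under test.
    """
    best = math.inf
    for k in range(int(90 / step_deg)):
        th = math.radians(k * step_deg)
        c, s = math.cos(th), math.sin(th)
        x = points[:, 0] * c - points[:, 1] * s
        y = points[:, 0] * s + points[:, 1] * c
        area = (x.max() - x.min() + inflation) * (y.max() - y.min() + inflation)
        best = min(best, area)
    return best


def foreground_centers(binary: np.ndarray) -> np.ndarray:
    """Foreground pixel centers, shape (n, 2), columns (x, y)."""
    ys, xs = np.nonzero(binary)
    return np.column_stack([xs, ys]).astype(float)


def pixel_corner_cloud(binary: np.ndarray) -> np.ndarray:
    """All four corners of every foreground pixel, shape (4n, 2), (x, y)."""
    ys, xs = np.nonzero(binary)
    centers = np.column_stack([xs, ys]).astype(float)
    offsets = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    return (centers[:, None, :] + offsets[None, :, :]).reshape(-1, 2)


def integrate_crossing(Vy1: float, a: float, d: float, decelerate: bool, dt: float = 1e-5):
    """Step-wise integrator of the constant-friction crossing ODE.

    Returns (Vy2, t) when the lateral position reaches ``d``; oracle for
    the closed-form kinematics.  ``decelerate`` selects the friction sign.
    """
    y, v, t = 0.0, Vy1, 0.0
    sign = -1.0 if decelerate else 1.0
    while y < d:
        if decelerate and v <= 0:
            return 0.0, t  # stalled before the edge
        y += v * dt
        v += sign * a * dt
        t += dt
    return v, t


@pytest.fixture
def random_convex_blob():
    """Factory: a random filled convex blob rasterized on a <=64x64 grid."""

    def make(rng: np.random.Generator) -> np.ndarray:
        n_pts = int(rng.integers(3, 12))
        pts = rng.uniform(8, 56, size=(n_pts, 2))
        from scipy.spatial import ConvexHull, QhullError

        try:
            hull = ConvexHull(pts)
        except QhullError:
            return make(rng)
        poly = pts[hull.vertices]
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        inside = np.ones((64, 64), dtype=bool)
        m = len(poly)
        for i in range(m):
            x0, y0 = poly[i]
            x1, y1 = poly[(i + 1) % m]
            inside &= (x1 - x0) * (yy - y0) - (y1 - y0) * (xx - x0) >= 0
        if inside.sum() < 12:
            return make(rng)
        return inside

    return make
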