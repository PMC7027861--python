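"""Independent brute-force oracles used only by the tests.

These deliberately avoid the code paths they check: containment is a
textbook crossing-number (even-odd ray casting) test, and the bounding box
oracle is an exhaustive rotation scan instead of a hull-edge enumeration.
"""

import numpy as np


def crossing_number_inside(vertices: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Even-odd rule containment by horizontal ray casting (boundary excluded)."""
    v = np.asarray(vertices, float)
    x = np.atleast_1d(np.asarray(x, float))
    y = np.atleast_1d(np.asarray(y, float))
    x1, y1 = v[:, 0], v[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    inside = np.zeros(x.shape, dtype=bool)
    for i in range(len(v)):
        straddles = (y1[i] > y) != (y2[i] > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_cross = (x2[i] - x1[i]) * (y - y1[i]) / (y2[i] - y1[i]) + x1[i]
        inside ^= straddles & (x < x_cross)
    return inside


def bbox_angle_scan(points: np.ndarray, step_deg: float = 0.01):
    """Exhaustive enclosing-rectangle scan over 0..180 degrees.

    Returns (length, width, min_area) of the smallest enclosing rectangle
    found on the angle grid.
    """
    pts = np.asarray(points, float)
    theta = np.radians(np.arange(0.0, 180.0, step_deg))
    c, s = np.cos(theta), np.sin(theta)
    xr = c[:, None] * pts[None, :, 0] + s[:, None] * pts[None, :, 1]
    yr = -s[:, None] * pts[None, :, 0] + c[:, None] * pts[None, :, 1]
    w = xr.max(axis=1) - xr.min(axis=1)
    h = yr.max(axis=1) - yr.min(axis=1)
    area = w * h
    i = int(np.argmin(area))
    length = max(w[i], h[i])
    width = min(w[i], h[i])
    return float(length), float(width), float(area[i])


def shoelace(vertices: np.ndarray) -> float:
    v = np.asarray(vertices, float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def random_hull_polygon(rng: np.random.Generator, n_points: int = 12, scale: float = 20.0):
    """Random convex polygon: the hull of a Gaussian point cloud."""
    from scipy.spatial import ConvexHull

    while True:
        pts = rng.normal(scale=scale, size=(n_points, 2)) + rng.uniform(0, 100, size=2)
        try:
            hull = ConvexHull(pts)
        except Exception:
            continue
        return pts[hull.vertices]
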