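"""Exact geometric primitives for holistic shape phenotypes.

Minimum enclosing sphere via Welzl's randomized incremental algorithm
(run on convex-hull vertices for large clouds — the enclosing sphere is
determined by hull points only), and the minimum-area oriented rectangle
of a planar point set (rotating-calipers result via shapely), used for
the vertical-axis minimum bounding cuboid.
"""

from __future__ import annotations

import sys

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import MultiPoint

__all__ = ["min_enclosing_sphere", "min_oriented_rectangle_area"]

_EPS = 1e-10


def _sphere_2(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    c = (a + b) / 2.0
    return c, float(np.linalg.norm(a - c))


def _sphere_3(a: np.ndarray, b: np.ndarray, c: np.ndarray):
    # Circumcircle of a triangle embedded in 3D: centre = a + alpha*u + beta*v.
    u, v = b - a, c - a
    g = np.array([[u @ u, u @ v], [u @ v, v @ v]])
    rhs = np.array([u @ u, v @ v]) / 2.0
    det = np.linalg.det(g)
    if abs(det) < _EPS * max(1.0, (u @ u) * (v @ v)):
        return None
    alpha, beta = np.linalg.solve(g, rhs)
    centre = a + alpha * u + beta * v
    return centre, float(np.linalg.norm(a - centre))


def _sphere_4(a, b, c, d):
    m = 2.0 * np.stack([b - a, c - a, d - a])
    rhs = np.array([b @ b - a @ a, c @ c - a @ a, d @ d - a @ a])
    if abs(np.linalg.det(m)) < _EPS * max(1.0, float(np.abs(m).max()) ** 3):
        return None
    centre = np.linalg.solve(m, rhs)
    return centre, float(np.linalg.norm(a - centre))


def _sphere_from_support(R: list[np.ndarray]) -> tuple[np.ndarray, float]:
    """Sphere with every support point of R on its boundary (|R| <= 4).

    This is the constrained base case of Welzl's recursion: points in R
    were found outside earlier candidate spheres, so they must lie ON
    the boundary (circumcircle for three points, circumsphere for four),
    not merely inside.  Degenerate (collinear/coplanar) support sets
    fall back to the smallest enclosing sphere of R.
    """
    if not R:
        return np.zeros(3), 0.0
    if len(R) == 1:
        return R[0].copy(), 0.0
    if len(R) == 2:
        return _sphere_2(R[0], R[1])
    if len(R) == 3:
        s = _sphere_3(R[0], R[1], R[2])
        if s is not None:
            return s
    if len(R) == 4:
        s = _sphere_4(*R)
        if s is not None:
            return s
    # Degenerate support: smallest sphere enclosing R from subsets.
    import itertools

    candidates = [
        _sphere_2(R[i], R[j])
        for i, j in itertools.combinations(range(len(R)), 2)
    ]
    for tri in itertools.combinations(range(len(R)), 3):
        s = _sphere_3(R[tri[0]], R[tri[1]], R[tri[2]])
        if s is not None:
            candidates.append(s)
    best = None
    for c, r in candidates:
        if all(np.linalg.norm(p - c) <= r * (1 + _EPS) + _EPS for p in R):
            if best is None or r < best[1]:
                best = (c, r)
    if best is None:  # numerically desperate: centroid bound
        c = np.mean(R, axis=0)
        return c, float(max(np.linalg.norm(p - c) for p in R))
    return best


def _welzl(pts: np.ndarray, idx: int, R: list[np.ndarray]) -> tuple[np.ndarray, float]:
    if idx == 0 or len(R) == 4:
        return _sphere_from_support(R)
    p = pts[idx - 1]
    c, r = _welzl(pts, idx - 1, R)
    if np.linalg.norm(p - c) <= r * (1 + _EPS) + _EPS:
        return c, r
    return _welzl(pts, idx - 1, R + [p])


def min_enclosing_sphere(points: np.ndarray, seed: int = 0) -> tuple[np.ndarray, float]:
    """Exact minimum enclosing sphere of a 3D point set.

    Welzl's randomized incremental construction; for clouds with more
    than a few hundred points the input is first reduced to its convex
    hull vertices (which determine the sphere).  Deterministic: the
    internal shuffle is seeded.

    Returns ``(center, radius)``; a single point yields radius 0.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("empty point set")
    pts = np.unique(pts, axis=0)
    if len(pts) == 1:
        return pts[0].copy(), 0.0
    if len(pts) > 300:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            pass  # degenerate (coplanar/collinear); Welzl handles it directly
    rng = np.random.default_rng(seed)
    pts = pts[rng.permutation(len(pts))]
    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 4 * len(pts) + 1000))
    try:
        c, r = _welzl(pts, len(pts), [])
    finally:
        sys.setrecursionlimit(old_limit)
    return c, float(r)


def min_oriented_rectangle_area(points_xy: np.ndarray) -> float:
    """Area of the minimum-area oriented rectangle enclosing planar points.

    Exact (rotating-calipers optimum over hull edges).  Degenerate sets
    (collinear or single point) have area 0.
    """
    xy = np.asarray(points_xy, dtype=float).reshape(-1, 2)
    if len(xy) == 0:
        raise ValueError("empty point set")
    rect = MultiPoint(xy).minimum_rotated_rectangle
    return float(getattr(rect, "area", 0.0))
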