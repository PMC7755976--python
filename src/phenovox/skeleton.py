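"""Leaf skeleton extraction and 3D leaf length.

Each separated leaf (a tube/ribbon of voxel centres) is thinned to a 1D
curve by Laplacian-based contraction: a k-nearest-neighbour graph is
built over the points, and each iteration solves a sparse least-squares
system balancing a contraction term (the graph Laplacian pulls points
toward local neighbourhood centroids) against an attraction term
(anchors near previous positions).  The contraction weight grows each
iteration while per-point attraction weights rise with local shrinkage,
so the cloud collapses onto its medial curve without drifting.

The contracted points are then projected onto the leaf's principal
plane (first two PCA axes), an n-th order polynomial y = p(x) is fitted
by least squares, and leaf length is the arc length of that curve,

    L = integral over [x1, x2] of sqrt(1 + p'(x)^2) dx,

where x1, x2 are the extreme skeleton x-coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.integrate import quad
from scipy.sparse.linalg import spsolve
from scipy.spatial import cKDTree

__all__ = [
    "ContractionParams",
    "LeafSkeleton",
    "laplacian_contract",
    "fit_leaf_curve",
    "arc_length",
    "leaf_length",
]


@dataclass
class ContractionParams:
    """Hyperparameters of the Laplacian contraction.

    ``thin_tol`` is in the units of the input points (voxel edges for
    grid clouds): iteration stops once the mean distance of points to
    their local best-fit line drops below it.
    """

    k_neighbors: int = 8
    growth: float = 2.0
    max_iter: int = 10
    thin_tol: float = 0.5
    min_points: int = 20
    init_contraction: float = 1.0
    init_attraction: float = 1.0

    def to_dict(self) -> dict:
        return {
            "k_neighbors": self.k_neighbors,
            "growth": self.growth,
            "max_iter": self.max_iter,
            "thin_tol": self.thin_tol,
            "min_points": self.min_points,
            "init_contraction": self.init_contraction,
            "init_attraction": self.init_attraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ContractionParams":
        return cls(**d)


@dataclass
class LeafSkeleton:
    """A leaf's skeleton curve in its principal plane.

    ``plane_basis`` rows are the two orthonormal principal axes (x-axis
    first); ``curve2d`` are the contracted points in plane coordinates;
    ``poly_coeffs`` are highest-power-first coefficients of the fitted
    polynomial y = p(x) over ``x_range``.
    """

    raw_points: np.ndarray
    plane_basis: np.ndarray
    plane_origin: np.ndarray
    curve2d: np.ndarray
    poly_coeffs: np.ndarray
    order: int
    x_range: tuple[float, float]
    residual_rms: float
    out_of_plane_rms: float

    def __post_init__(self) -> None:
        x1, x2 = self.x_range
        if not x1 < x2:
            raise ValueError("x_range must satisfy x1 < x2")
        if self.order < 1:
            raise ValueError("polynomial order must be >= 1")


def _thickness(points: np.ndarray, tree_k: int = 16) -> float:
    """Mean distance of each point to the best-fit line of its kNN set.

    The neighbourhood is kept larger than the contraction's own kNN
    graph: with few neighbours the local line overfits a noisy tube and
    under-reports its width.
    """
    n = len(points)
    k = min(max(tree_k, 16) + 1, n)
    tree = cKDTree(points)
    _, nbr = tree.query(points, k=k)
    dists = np.empty(n)
    for i in range(n):
        local = points[nbr[i]]
        c = local.mean(axis=0)
        centered = local - c
        # First principal axis of the local neighbourhood.
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
        rel = points[i] - c
        dists[i] = np.linalg.norm(rel - (rel @ axis) * axis)
    return float(dists.mean())


def laplacian_contract(
    points: np.ndarray, params: ContractionParams | None = None
) -> np.ndarray:
    """Contract a point cloud toward its medial curve.

    Returns contracted points with the same cardinality as the input.
    Raises ``ValueError`` when fewer than ``params.min_points`` points
    are supplied.  If the linear system turns singular the routine falls
    back to a single PCA-line projection with a warning.
    """
    params = params or ContractionParams()
    raw = np.asarray(points, dtype=float).reshape(-1, 3)
    n = len(raw)
    if n < params.min_points:
        raise ValueError(
            f"need at least {params.min_points} points, got {n}"
        )
    # Normalize by the median nearest-neighbour spacing so the procedure
    # (and thin_tol, expressed in point-spacing units, i.e. voxel edges
    # for grid clouds) is scale-equivariant.  A no-op for unit lattices.
    nn = cKDTree(raw).query(raw, k=2)[0][:, 1]
    scale = float(np.median(nn)) or 1.0
    pts = raw / scale
    if _thickness(pts, params.k_neighbors) < params.thin_tol:
        return raw.copy()  # already 1D: fixed point

    k = min(params.k_neighbors + 1, n)
    tree = cKDTree(pts)
    dist, nbr = tree.query(pts, k=k)
    rows = np.repeat(np.arange(n), k - 1)
    cols = nbr[:, 1:].ravel()
    w = 1.0 / (dist[:, 1:].ravel() + 1e-9)
    W = sparse.coo_matrix((w, (rows, cols)), shape=(n, n))
    W = (W + W.T) * 0.5  # symmetrize the fixed neighbourhood graph
    deg = np.asarray(W.sum(axis=1)).ravel()
    # Row-normalized Laplacian: Lx drives points toward weighted
    # neighbourhood centroids.
    L = sparse.eye(n) - sparse.diags(1.0 / np.maximum(deg, 1e-12)) @ W

    orig_spread = dist[:, 1:].mean(axis=1)
    w_l = params.init_contraction
    w_h = np.full(n, params.init_attraction)
    cur = pts.copy()
    for _ in range(params.max_iter):
        A = (w_l**2) * (L.T @ L) + sparse.diags(w_h**2)
        B = sparse.diags(w_h**2) @ cur
        try:
            new = spsolve(A.tocsc(), B)
        except Exception:
            warnings.warn(
                "contraction system singular; falling back to PCA-line projection",
                stacklevel=2,
            )
            c = raw.mean(axis=0)
            _, _, vt = np.linalg.svd(raw - c, full_matrices=False)
            axis = vt[0]
            return c + ((raw - c) @ axis)[:, None] * axis
        new = np.asarray(new).reshape(n, 3)
        if not np.all(np.isfinite(new)):
            warnings.warn(
                "contraction diverged; falling back to PCA-line projection",
                stacklevel=2,
            )
            c = raw.mean(axis=0)
            _, _, vt = np.linalg.svd(raw - c, full_matrices=False)
            axis = vt[0]
            return c + ((raw - c) @ axis)[:, None] * axis
        cur = new
        if _thickness(cur, params.k_neighbors) < params.thin_tol:
            break
        w_l *= params.growth
        d2, nb2 = cKDTree(cur).query(cur, k=k)
        spread = d2[:, 1:].mean(axis=1)
        shrink = orig_spread / np.maximum(spread, 1e-9)
        w_h = params.init_attraction * np.sqrt(np.maximum(shrink, 1.0))
    return cur * scale


def fit_leaf_curve(contracted: np.ndarray, order: int = 4) -> LeafSkeleton:
    """Fit y = p(x) to contracted points in their PCA principal plane.

    The plane is spanned by the first two principal axes of the point
    set (x = dominant axis); out-of-plane residual RMS is recorded as a
    quality metric.  If the requested order reaches the number of
    distinct x values it is reduced with a warning.
    """
    pts = np.asarray(contracted, dtype=float).reshape(-1, 3)
    if len(pts) < 2:
        raise ValueError("need at least 2 points to fit a curve")
    c = pts.mean(axis=0)
    centered = pts - c
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    basis = vt[:2]
    # Deterministic sign convention: largest-magnitude loading positive.
    for row in range(2):
        j = int(np.argmax(np.abs(basis[row])))
        if basis[row, j] < 0:
            basis[row] = -basis[row]
    xy = centered @ basis.T
    out_of_plane = (
        centered @ vt[2] if vt.shape[0] > 2 else np.zeros(len(pts))
    )
    x, y = xy[:, 0], xy[:, 1]
    distinct = len(np.unique(np.round(x, 9)))
    eff_order = order
    if order >= distinct:
        eff_order = max(1, distinct - 1)
        warnings.warn(
            f"order {order} >= {distinct} distinct x values; reduced to {eff_order}",
            stacklevel=2,
        )
    coeffs = np.polyfit(x, y, eff_order)
    resid = y - np.polyval(coeffs, x)
    x1, x2 = float(x.min()), float(x.max())
    if x1 == x2:
        raise ValueError("degenerate curve: zero x extent in the principal plane")
    return LeafSkeleton(
        raw_points=pts,
        plane_basis=basis,
        plane_origin=c,
        curve2d=xy,
        poly_coeffs=coeffs,
        order=eff_order,
        x_range=(x1, x2),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        out_of_plane_rms=float(np.sqrt(np.mean(out_of_plane**2))),
    )


def arc_length(skel: LeafSkeleton, edge: float = 1.0) -> float:
    """Arc length of the fitted skeleton curve, converted to mm by ``edge``.

    Numerical quadrature of sqrt(1 + p'(x)^2) over the skeleton's x
    range, relative tolerance 1e-8.
    """
    dp = np.polyder(skel.poly_coeffs)
    x1, x2 = skel.x_range
    val, _ = quad(
        lambda x: np.sqrt(1.0 + np.polyval(dp, x) ** 2),
        x1,
        x2,
        epsrel=1e-8,
        limit=200,
    )
    return float(val) * edge


def leaf_length(
    points: np.ndarray,
    params: ContractionParams | None = None,
    order: int = 4,
    edge: float = 1.0,
) -> float:
    """3D leaf length: contract -> plane fit -> arc length (mm)."""
    contracted = laplacian_contract(points, params)
    skel = fit_leaf_curve(contracted, order=order)
    return arc_length(skel, edge=edge)


def skeleton_polyline(skel: LeafSkeleton, n_samples: int = 100) -> np.ndarray:
    """Sample the fitted curve back into 3D world coordinates."""
    x = np.linspace(skel.x_range[0], skel.x_range[1], n_samples)
    y = np.polyval(skel.poly_coeffs, x)
    pts2d = np.stack([x, y], axis=1)
    return skel.plane_origin + pts2d @ skel.plane_basis
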