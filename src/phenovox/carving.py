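"""Silhouette-based space carving on an axis-aligned voxel grid.

Starting from a fully occupied grid covering the scene, each calibrated
view removes ("carves") every voxel whose projection falls outside that
view's plant silhouette.  The surviving occupancy is the visual hull —
the maximal shape consistent with all silhouettes — which always
contains the true object and tightens monotonically as views are added.
Only silhouette consistency is used; no colour/photo-consistency test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from phenovox.cameras import CameraView, project
from phenovox.segmentation import Silhouette

__all__ = [
    "VoxelGrid",
    "PlantCloud",
    "init_grid",
    "carve_view",
    "carve",
    "to_plant_cloud",
    "largest_component",
]


@dataclass
class VoxelGrid:
    """Axis-aligned occupancy grid.

    ``occupancy[i, j, k]`` covers the world-space cube whose centre is
    ``origin + edge * (i + 0.5, j + 0.5, k + 0.5)``; indices are 0-based
    and run along x, y, z respectively.
    """

    dims: tuple[int, int, int]
    origin: np.ndarray
    edge: float
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.shape != tuple(self.dims):
            raise ValueError("occupancy shape does not match dims")
        if self.edge <= 0:
            raise ValueError("edge must be positive")

    @property
    def count(self) -> int:
        return int(self.occupancy.sum())

    def occupied_indices(self) -> np.ndarray:
        """(n, 3) int array of occupied voxel indices (i, j, k)."""
        return np.argwhere(self.occupancy)

    def centers(self, indices: np.ndarray | None = None) -> np.ndarray:
        """World-space centres (mm) of the given (or all occupied) voxels."""
        idx = self.occupied_indices() if indices is None else np.asarray(indices)
        return self.origin + self.edge * (idx + 0.5)

    def copy_with(self, occupancy: np.ndarray) -> "VoxelGrid":
        return VoxelGrid(self.dims, self.origin.copy(), self.edge, occupancy)


@dataclass
class PlantCloud:
    """The reconstructed plant as a set of occupied voxel indices.

    ``points`` is an (n, 3) int array of (i, j, k) indices; grid
    metadata is carried along so world coordinates stay recoverable.
    """

    points: np.ndarray
    dims: tuple[int, int, int]
    origin: np.ndarray
    edge: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.int64).reshape(-1, 3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    def __len__(self) -> int:
        return len(self.points)

    def centers_mm(self, indices: np.ndarray | None = None) -> np.ndarray:
        idx = self.points if indices is None else np.asarray(indices)
        return self.origin + self.edge * (idx + 0.5)


def init_grid(
    bounds: tuple[tuple[float, float, float], tuple[float, float, float]],
    resolution: tuple[int, int, int],
) -> VoxelGrid:
    """Fully occupied grid covering a world-space box.

    ``bounds`` is ``((xmin, ymin, zmin), (xmax, ymax, zmax))`` in mm.
    The box must be divisible into cubic voxels: the per-axis extents
    divided by the per-axis counts must agree.
    """
    lo = np.asarray(bounds[0], dtype=float)
    hi = np.asarray(bounds[1], dtype=float)
    res = tuple(int(r) for r in resolution)
    if any(r <= 0 for r in res):
        raise ValueError("resolution must be positive in all axes")
    if np.any(hi <= lo):
        raise ValueError("bounds must have positive extent in all axes")
    edges = (hi - lo) / np.array(res, dtype=float)
    if not np.allclose(edges, edges[0], rtol=1e-9, atol=1e-12):
        raise ValueError("bounds/resolution must yield cubic voxels (equal edge)")
    return VoxelGrid(
        dims=res,
        origin=lo,
        edge=float(edges[0]),
        occupancy=np.ones(res, dtype=bool),
    )


def _lookup(sil_mask: np.ndarray, uv: np.ndarray, in_front: np.ndarray) -> np.ndarray:
    """Nearest-pixel silhouette test; out-of-bounds/behind count as outside."""
    h, w = sil_mask.shape
    inside = np.zeros(len(uv), dtype=bool)
    ok = in_front & np.all(np.isfinite(uv), axis=1)
    if not ok.any():
        return inside
    u = np.rint(uv[ok, 0]).astype(np.int64)
    v = np.rint(uv[ok, 1]).astype(np.int64)
    in_img = (u >= 0) & (u < w) & (v >= 0) & (v < h)
    hit = np.zeros(ok.sum(), dtype=bool)
    hit[in_img] = sil_mask[v[in_img], u[in_img]]
    inside[ok] = hit
    return inside


_CORNER_OFFSETS = np.array(
    [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)], dtype=float
)


def carve_view(
    grid: VoxelGrid,
    sil: Silhouette,
    cam: CameraView,
    footprint: str = "center",
) -> VoxelGrid:
    """Remove occupied voxels whose footprint projects outside one silhouette.

    ``footprint="center"`` (default): a voxel survives iff its centre
    projects to a foreground pixel (nearest-pixel lookup).
    ``footprint="conservative"``: the 8 corners are projected and the
    voxel survives if any corner lands inside.  Voxels behind the camera
    are treated as outside (removed) and counted in a warning.  Pure
    function of its inputs and order-independent across views.
    """
    if footprint not in ("center", "conservative"):
        raise ValueError("footprint must be 'center' or 'conservative'")
    mask = np.asarray(sil.mask, dtype=bool)
    h, w = mask.shape
    if (w, h) != tuple(cam.image_size):
        raise ValueError("silhouette size does not match camera image_size")
    idx = grid.occupied_indices()
    if len(idx) == 0:
        return grid.copy_with(np.zeros(grid.dims, dtype=bool))
    if footprint == "center":
        uv, in_front = project(grid.centers(idx), cam)
        keep = _lookup(mask, uv, in_front)
        n_behind = int((~in_front).sum())
    else:
        keep = np.zeros(len(idx), dtype=bool)
        n_behind = 0
        for off in _CORNER_OFFSETS:
            corners = grid.origin + grid.edge * (idx + off)
            uv, in_front = project(corners, cam)
            keep |= _lookup(mask, uv, in_front)
        _, in_front_c = project(grid.centers(idx), cam)
        n_behind = int((~in_front_c).sum())
    if n_behind:
        warnings.warn(
            f"{n_behind} voxel(s) projected behind camera {cam.view_id}; removed",
            stacklevel=2,
        )
    occ = np.zeros(grid.dims, dtype=bool)
    kept = idx[keep]
    occ[kept[:, 0], kept[:, 1], kept[:, 2]] = True
    return grid.copy_with(occ)


def carve(
    grid: VoxelGrid,
    views: list[tuple[Silhouette, CameraView]],
    footprint: str = "center",
) -> VoxelGrid:
    """Sequential fold of :func:`carve_view` over all views.

    The result is the per-view intersection, hence independent of view
    order, idempotent under duplicated views, and non-increasing in the
    number of views.
    """
    out = grid
    for sil, cam in views:
        out = carve_view(out, sil, cam, footprint=footprint)
    return out


def to_plant_cloud(grid: VoxelGrid) -> PlantCloud:
    """The plant point set P = all occupied voxel indices."""
    return PlantCloud(
        points=grid.occupied_indices(),
        dims=grid.dims,
        origin=grid.origin,
        edge=grid.edge,
    )


def largest_component(cloud: PlantCloud, connectivity: int = 26) -> PlantCloud:
    """Keep only the largest connected component of the cloud.

    Guards the organ-separation stage against floating carving debris.
    ``connectivity`` is 6, 18 or 26 (3D neighbourhood).
    """
    if len(cloud) == 0:
        return cloud
    structure = {
        6: ndimage.generate_binary_structure(3, 1),
        18: ndimage.generate_binary_structure(3, 2),
        26: ndimage.generate_binary_structure(3, 3),
    }[connectivity]
    occ = np.zeros(cloud.dims, dtype=bool)
    occ[cloud.points[:, 0], cloud.points[:, 1], cloud.points[:, 2]] = True
    labels, n = ndimage.label(occ, structure=structure)
    if n <= 1:
        return cloud
    counts = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(counts)) + 1
    return PlantCloud(
        points=np.argwhere(labels == best),
        dims=cloud.dims,
        origin=cloud.origin,
        edge=cloud.edge,
    )
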