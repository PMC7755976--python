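"""Space carving: oracle equivalence, hull properties, set semantics.

The brute-force oracle below re-derives the projection and silhouette
test per voxel with scalar math, independently of the vectorized
implementation, so the two can be compared voxel-for-voxel.
"""

import math

import numpy as np
import pytest

from phenovox.cameras import CameraView, make_turntable_cameras
from phenovox.carving import (
    VoxelGrid,
    carve,
    carve_view,
    init_grid,
    largest_component,
    to_plant_cloud,
)
from phenovox.segmentation import Silhouette


def brute_force_carve(grid: VoxelGrid, views) -> set:
    """Scalar per-voxel reimplementation of silhouette-consistency carving."""
    survivors = set()
    for (i, j, k) in map(tuple, grid.occupied_indices()):
        cx3 = grid.origin[0] + grid.edge * (i + 0.5)
        cy3 = grid.origin[1] + grid.edge * (j + 0.5)
        cz3 = grid.origin[2] + grid.edge * (k + 0.5)
        ok = True
        for sil, cam in views:
            R, t = cam.rotation, cam.translation
            X = R[0, 0] * cx3 + R[0, 1] * cy3 + R[0, 2] * cz3 + t[0]
            Y = R[1, 0] * cx3 + R[1, 1] * cy3 + R[1, 2] * cz3 + t[1]
            Z = R[2, 0] * cx3 + R[2, 1] * cy3 + R[2, 2] * cz3 + t[2]
            if Z <= 0:
                ok = False
                break
            x, y = X / Z, Y / Z
            k1, k2 = cam.radial_distortion
            p1, p2 = cam.tangential_distortion
            r2 = x * x + y * y
            rad = 1 + k1 * r2 + k2 * r2 * r2
            xd = x * rad + 2 * p1 * x * y + p2 * (r2 + 2 * x * x)
            yd = y * rad + p1 * (r2 + 2 * y * y) + 2 * p2 * x * y
            u = cam.focal[0] * xd + cam.skew * yd + cam.principal_point[0]
            v = cam.focal[1] * yd + cam.principal_point[1]
            ui, vi = round(u), round(v)
            h, w = sil.mask.shape
            if not (0 <= ui < w and 0 <= vi < h and sil.mask[vi, ui]):
                ok = False
                break
        if ok:
            survivors.add((i, j, k))
    return survivors


def sphere_silhouettes(n_views, grid, center, radius_mm, image_size=(160, 160)):
    """Exact analytic silhouettes of a sphere for a camera ring."""
    cams = make_turntable_cameras(
        n_views, radius=600.0, height=center[2], focal=300.0,
        image_size=image_size, target=center,
    )
    views = []
    for cam in cams:
        h, w = image_size[1], image_size[0]
        vv, uu = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        # Ray through each pixel: inside silhouette iff the ray passes
        # within radius of the sphere centre.
        x = (uu - cam.principal_point[0]) / cam.focal[0]
        y = (vv - cam.principal_point[1]) / cam.focal[1]
        dirs = np.stack([x, y, np.ones_like(x)], axis=-1) @ cam.rotation
        dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)
        o = cam.center
        rel = np.asarray(center, float) - o
        tproj = dirs @ rel
        closest = np.linalg.norm(rel[None, None, :] - tproj[..., None] * dirs, axis=-1)
        mask = (closest <= radius_mm) & (tproj > 0)
        views.append((Silhouette(mask=mask, view_id=cam.view_id), cam))
    return views


class TestInitGrid:
    def test_full_occupancy_count(self):
        g = init_grid(((0, 0, 0), (10, 10, 10)), (10, 10, 10))
        assert g.count == 1000 and g.edge == 1.0

    def test_paper_scale_edge(self):
        g = init_grid(((0, 0, 0), (1200.0, 1200.0, 1200.0)), (1200, 1200, 1200))
        assert g.edge == 1.0
        assert g.count == 1200**3

    def test_non_positive_resolution_rejected(self):
        with pytest.raises(ValueError):
            init_grid(((0, 0, 0), (1, 1, 1)), (0, 5, 5))

    def test_non_cubic_voxels_rejected(self):
        with pytest.raises(ValueError):
            init_grid(((0, 0, 0), (10, 20, 10)), (10, 10, 10))


class TestCarveView:
    def _setup(self):
        g = init_grid(((-8, -8, -8), (8, 8, 8)), (16, 16, 16))
        cam = make_turntable_cameras(
            2, radius=100.0, focal=200.0, image_size=(64, 64)
        )[0]
        return g, cam

    def test_all_white_silhouette_is_noop(self):
        g, cam = self._setup()
        sil = Silhouette(np.ones((64, 64), bool), cam.view_id)
        assert carve_view(g, sil, cam).count == g.count

    def test_all_black_silhouette_empties_grid(self):
        g, cam = self._setup()
        sil = Silhouette(np.zeros((64, 64), bool), cam.view_id)
        assert carve_view(g, sil, cam).count == 0

    def test_single_view_matches_brute_force_exactly(self, rng):
        g, cam = self._setup()
        mask = rng.uniform(size=(64, 64)) > 0.5
        sil = Silhouette(mask, cam.view_id)
        carved = carve_view(g, sil, cam)
        got = set(map(tuple, carved.occupied_indices()))
        assert got == brute_force_carve(g, [(sil, cam)])

    def test_conservative_footprint_matches_any_corner_rule(self, rng):
        from phenovox.cameras import project

        g, cam = self._setup()
        mask = rng.uniform(size=(64, 64)) > 0.6
        sil = Silhouette(mask, cam.view_id)
        conserv = set(
            map(tuple, carve_view(g, sil, cam, "conservative").occupied_indices())
        )
        expected = set()
        for idx in map(tuple, g.occupied_indices()):
            hit = False
            for di in (0, 1):
                for dj in (0, 1):
                    for dk in (0, 1):
                        corner = g.origin + g.edge * np.array(
                            [idx[0] + di, idx[1] + dj, idx[2] + dk], float
                        )
                        uv, ok = project(corner, cam)
                        if not ok:
                            continue
                        u, v = int(round(uv[0])), int(round(uv[1]))
                        if 0 <= u < 64 and 0 <= v < 64 and mask[v, u]:
                            hit = True
            if hit:
                expected.add(idx)
        assert conserv == expected


class TestCarve:
    def test_visual_hull_contains_sphere_and_matches_oracle(self):
        center = (0.0, 0.0, 0.0)
        g = init_grid(((-10, -10, -10), (10, 10, 10)), (20, 20, 20))
        views = sphere_silhouettes(4, g, center, radius_mm=6.0)
        carved = carve(g, views)
        got = set(map(tuple, carved.occupied_indices()))
        assert got == brute_force_carve(g, views)
        # Superset: every voxel whose centre is inside the sphere survives.
        centers = g.centers(g.occupied_indices())
        inside = np.linalg.norm(centers - center, axis=1) <= 6.0
        true_vox = set(map(tuple, g.occupied_indices()[inside]))
        assert true_vox <= got

    def test_duplicate_view_idempotent(self):
        g = init_grid(((-10, -10, -10), (10, 10, 10)), (20, 20, 20))
        views = sphere_silhouettes(2, g, (0, 0, 0), 6.0)
        once = carve(g, views[:1])
        twice = carve(g, [views[0], views[0]])
        assert np.array_equal(once.occupancy, twice.occupancy)

    def test_view_order_invariance(self):
        g = init_grid(((-10, -10, -10), (10, 10, 10)), (20, 20, 20))
        views = sphere_silhouettes(4, g, (0, 0, 0), 6.0)
        a = carve(g, views)
        b = carve(g, views[::-1])
        assert np.array_equal(a.occupancy, b.occupancy)

    def test_monotonic_in_views(self):
        g = init_grid(((-10, -10, -10), (10, 10, 10)), (20, 20, 20))
        views = sphere_silhouettes(6, g, (0, 0, 0), 6.0)
        counts = [carve(g, views[:n]).count for n in (1, 2, 4, 6)]
        assert counts == sorted(counts, reverse=True)
        occ_all = carve(g, views).occupancy
        occ_half = carve(g, views[:3]).occupancy
        assert not np.any(occ_all & ~occ_half)  # subset

    def test_behind_camera_voxels_removed_with_warning(self):
        g = init_grid(((-8, -8, -8), (8, 8, 8)), (8, 8, 8))
        cam = CameraView(
            view_id="inside",
            azimuth_deg=0.0,
            focal=(100.0, 100.0),
            principal_point=(32.0, 32.0),
            rotation=np.eye(3),
            translation=np.zeros(3),  # camera at the grid centre
            image_size=(64, 64),
        )
        sil = Silhouette(np.ones((64, 64), bool), "inside")
        with pytest.warns(UserWarning, match="behind"):
            carved = carve_view(g, sil, cam)
        assert carved.count < g.count


class TestCloudOps:
    def test_plant_cloud_is_occupied_set(self):
        g = init_grid(((0, 0, 0), (4, 4, 4)), (4, 4, 4))
        cloud = to_plant_cloud(g)
        assert len(cloud) == 64

    def test_largest_component_filters_debris(self):
        occ = np.zeros((20, 20, 20), bool)
        occ[2:7, 2:7, 2:6] = True  # 100 voxels
        occ[15:16, 15:16, 15:20] = True  # 5 voxel rod, disconnected
        g = VoxelGrid((20, 20, 20), np.zeros(3), 1.0, occ)
        kept = largest_component(to_plant_cloud(g))
        assert len(kept) == 100

    def test_single_blob_unchanged(self):
        occ = np.zeros((10, 10, 10), bool)
        occ[1:5, 1:5, 1:5] = True
        g = VoxelGrid((10, 10, 10), np.zeros(3), 1.0, occ)
        assert len(largest_component(to_plant_cloud(g))) == 64

    def test_empty_grid_empty_cloud(self):
        g = VoxelGrid((4, 4, 4), np.zeros(3), 1.0, np.zeros((4, 4, 4), bool))
        assert len(largest_component(to_plant_cloud(g))) == 0
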