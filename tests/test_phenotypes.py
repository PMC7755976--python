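"""Holistic and component phenotypes: geometry oracles and invariants."""

import itertools
import math

import numpy as np
import pytest

from phenovox.carving import PlantCloud, to_plant_cloud
from phenovox.geometry import min_enclosing_sphere
from phenovox.phenotypes import (
    aspect_ratios,
    bounding_cuboid,
    compute_phenotypes,
    convex_hull_volume,
    min_bounding_cuboid_volume,
    min_enclosing_sphere_volume,
    occupancy_ratio,
    plant_volume,
    stem_phenotypes,
    trajectory,
)
from phenovox.separation import separate


def cloud_of(points, dims=(64, 64, 64)) -> PlantCloud:
    return PlantCloud(
        points=np.asarray(points, dtype=np.int64),
        dims=dims,
        origin=np.zeros(3),
        edge=1.0,
    )


def brute_force_mes(pts: np.ndarray) -> float:
    """Smallest enclosing sphere radius by exhaustive support-set search."""
    n = len(pts)
    best = math.inf

    def encloses(c, r):
        return np.all(np.linalg.norm(pts - c, axis=1) <= r + 1e-9)

    for i, j in itertools.combinations(range(n), 2):
        c = (pts[i] + pts[j]) / 2
        r = np.linalg.norm(pts[i] - c)
        if r < best and encloses(c, r):
            best = r
    for i, j, k in itertools.combinations(range(n), 3):
        a, b, c3 = pts[i], pts[j], pts[k]
        u, v = b - a, c3 - a
        g = np.array([[u @ u, u @ v], [u @ v, v @ v]])
        if abs(np.linalg.det(g)) < 1e-12:
            continue
        ab = np.linalg.solve(g, np.array([u @ u, v @ v]) / 2)
        cc = a + ab[0] * u + ab[1] * v
        r = np.linalg.norm(a - cc)
        if r < best and encloses(cc, r):
            best = r
    for i, j, k, l in itertools.combinations(range(n), 4):
        a, b, c3, d = pts[i], pts[j], pts[k], pts[l]
        m = 2 * np.stack([b - a, c3 - a, d - a])
        if abs(np.linalg.det(m)) < 1e-12:
            continue
        cc = np.linalg.solve(m, np.array([b @ b - a @ a, c3 @ c3 - a @ a, d @ d - a @ a]))
        r = np.linalg.norm(a - cc)
        if r < best and encloses(cc, r):
            best = r
    return best


class TestBasicVolumes:
    def test_empty_cloud_volume_zero(self):
        assert plant_volume(cloud_of(np.empty((0, 3)))) == 0

    def test_full_cube_count(self):
        pts = [(i, j, k) for i in range(10) for j in range(10) for k in range(10)]
        assert plant_volume(cloud_of(pts)) == 1000

    def test_cuboid_occupancy_ratio_approaches_one(self):
        """Solid n^3 cuboid: hull of centres has volume (n-1)^3, so the
        ratio is exactly (n/(n-1))^3 and decreases toward 1 with n."""
        ratios = []
        for n in (10, 20):
            pts = [(i, j, k) for i in range(n) for j in range(n) for k in range(n)]
            r = occupancy_ratio(cloud_of(pts))
            assert r == pytest.approx((n / (n - 1)) ** 3, rel=1e-9)
            ratios.append(r)
        assert ratios[1] < ratios[0]

    def test_tetrahedron_hull_volume_closed_form(self):
        # Corner tetrahedron (0,0,0),(6,0,0),(0,6,0),(0,0,6): V = 6^3/6 = 36.
        pts = [(0, 0, 0), (6, 0, 0), (0, 6, 0), (0, 0, 6)]
        assert convex_hull_volume(cloud_of(pts)) == pytest.approx(36.0)
        assert occupancy_ratio(cloud_of(pts)) == pytest.approx(4 / 36.0)

    def test_degenerate_cloud_reported_missing(self):
        pts = [(i, 0, 0) for i in range(10)]  # collinear
        assert math.isnan(convex_hull_volume(cloud_of(pts)))
        assert math.isnan(occupancy_ratio(cloud_of(pts)))


class TestMinEnclosingSphere:
    def test_single_point_zero_radius(self):
        c, r = min_enclosing_sphere(np.array([[1.0, 2.0, 3.0]]))
        assert r == 0.0 and np.allclose(c, [1, 2, 3])

    def test_two_points_diameter(self):
        c, r = min_enclosing_sphere(np.array([[0.0, 0, 0], [0, 0, 10.0]]))
        assert r == pytest.approx(5.0) and np.allclose(c, [0, 0, 5])

    def test_matches_exhaustive_support_search(self, rng):
        for trial in range(6):
            pts = rng.uniform(-10, 10, (30, 3))
            _, r = min_enclosing_sphere(pts)
            assert r == pytest.approx(brute_force_mes(pts), abs=1e-9)

    def test_all_points_enclosed(self, rng):
        pts = rng.normal(0, 5, (4000, 3))
        c, r = min_enclosing_sphere(pts)
        assert np.max(np.linalg.norm(pts - c, axis=1)) <= r + 1e-9

    def test_volume_formula(self):
        pts = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert min_enclosing_sphere_volume(pts) == pytest.approx(4 / 3 * math.pi)


class TestBoundingCuboid:
    def test_cube_aspect_ratios_one(self):
        pts = [(i, j, k) for i in (0, 5) for j in (0, 5) for k in (0, 5)]
        h, w, d = bounding_cuboid(cloud_of(pts))
        assert (h, w, d) == (5.0, 5.0, 5.0)
        assert aspect_ratios(h, w, d) == (1.0, 1.0)

    def test_direct_substitution(self):
        # Extents z=200, horizontals 100 and 50: PARp = 2, PARs = 4.
        pts = [(0, 0, 0), (100, 50, 200)]
        h, w, d = bounding_cuboid(cloud_of(pts, dims=(256, 256, 256)))
        assert (h, w, d) == (200.0, 100.0, 50.0)
        assert aspect_ratios(h, w, d) == (2.0, 4.0)

    def test_width_is_longer_horizontal_regardless_of_axis(self):
        pts = [(0, 0, 0), (50, 100, 200)]  # y-extent is the longer one
        _, w, d = bounding_cuboid(cloud_of(pts, dims=(256, 256, 256)))
        assert (w, d) == (100.0, 50.0)

    def test_isotropic_scaling_invariance(self, rng):
        pts = rng.uniform(0, 20, (50, 3))
        h, w, d = bounding_cuboid(pts)
        h2, w2, d2 = bounding_cuboid(pts * 3.7)
        assert aspect_ratios(h, w, d) == pytest.approx(aspect_ratios(h2, w2, d2))

    def test_zero_extent_ratio_missing(self):
        pts = [(0, 0, 0), (0, 0, 10)]
        h, w, d = bounding_cuboid(cloud_of(pts))
        par_p, par_s = aspect_ratios(h, w, d)
        assert math.isnan(par_p) and math.isnan(par_s)


class TestMinBoundingCuboid:
    def test_axis_aligned_cuboid_is_its_own_box(self):
        pts = [(i, j, k) for i in (0, 10) for j in (0, 4) for k in (0, 7)]
        assert min_bounding_cuboid_volume(cloud_of(pts)) == pytest.approx(10 * 4 * 7)

    def test_rotation_about_z_invariance(self):
        corners = np.array(
            [(i, j, k) for i in (0, 10.0) for j in (0, 4.0) for k in (0, 7.0)]
        )
        theta = math.radians(45)
        R = np.array(
            [
                [math.cos(theta), -math.sin(theta), 0],
                [math.sin(theta), math.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        v0 = min_bounding_cuboid_volume(corners)
        v1 = min_bounding_cuboid_volume(corners @ R.T)
        assert v1 == pytest.approx(v0, rel=1e-9)

    def test_matches_fine_rotation_grid_search(self, rng):
        for _ in range(4):
            pts = rng.uniform(-10, 10, (25, 3))
            got = min_bounding_cuboid_volume(pts)
            xy = pts[:, :2]
            zext = pts[:, 2].max() - pts[:, 2].min()
            best = math.inf
            for deg in np.arange(0.0, 90.0, 0.1):
                t = math.radians(deg)
                rot = xy @ np.array(
                    [[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]]
                )
                ext = rot.max(axis=0) - rot.min(axis=0)
                best = min(best, ext[0] * ext[1] * zext)
            assert got <= best * (1 + 1e-9)
            assert got == pytest.approx(best, rel=0.005)

    def test_hull_leq_min_box_leq_axis_box(self, rng):
        pts = rng.uniform(0, 30, (200, 3))
        hull = convex_hull_volume(pts)
        mbc = min_bounding_cuboid_volume(pts)
        h, w, d = bounding_cuboid(pts)
        assert hull <= mbc + 1e-9 <= h * w * d + 1e-9


class TestStemPhenotypes:
    def test_vertical_rod(self):
        S = np.array([(5, 5, k) for k in range(10)])
        s_h, vol, mean_area, profile, rate = stem_phenotypes(S)
        assert s_h == 9.0 and vol == 10 and mean_area == 1.0
        assert all(a == 1 for _, a in profile)
        assert all(dr == 0 for _, dr in rate)
        heights = [h for h, _ in profile]
        assert heights == sorted(heights)

    def test_single_layer_stem_height_zero(self):
        S = np.array([(5, 5, 3), (5, 6, 3)])
        s_h, vol, *_ = stem_phenotypes(S)
        assert s_h == 0.0 and vol == 2

    def test_tapered_stem_area_profile_non_increasing(self, default_model):
        # On the generator's true stem the linear taper makes the
        # cross-section area monotone non-increasing with height.
        truth_stem = default_model.component_points(0)
        *_, profile_t, rate_t = stem_phenotypes(truth_stem)
        areas_t = np.array([a for _, a in profile_t])
        assert np.all(np.diff(areas_t) <= 0)
        assert all(dr <= 0 for _, dr in rate_t)
        # The traced stem ripples at leaf junctions but keeps the trend.
        comps = separate(to_plant_cloud(default_model.grid))
        *_, profile, _ = stem_phenotypes(comps.stem)
        areas = np.array([a for _, a in profile])
        assert np.polyfit(np.arange(len(areas)), areas, 1)[0] < 0


class TestRecordAndTrajectory:
    def test_record_conservation_and_counts(self, small_model):
        cloud = to_plant_cloud(small_model.grid)
        comps = separate(cloud)
        rec = compute_phenotypes(cloud, comps, plant_id="p1")
        assert rec.leaf_count == small_model.truth.leaf_count
        assert (
            rec.stem_volume + rec.tlc_volume + rec.total_leaf_volume + rec.debris_volume
            == rec.plant_voxels
        )
        assert rec.bc_width >= rec.bc_depth
        assert rec.par_secondary >= rec.par_primary
        assert rec.convexhull_volume <= rec.mbc_volume <= rec.bc_volume + 1e-9
        # The minimum enclosing sphere really encloses the cloud.
        assert rec.sphere_volume >= rec.convexhull_volume

    def test_constant_series_zero_rates(self):
        from phenovox.phenotypes import PhenotypeRecord

        recs = [
            PhenotypeRecord(plant_id="p", day=d, plant_voxels=100, bc_volume=50.0)
            for d in range(4)
        ]
        df = trajectory(recs)
        assert (df["plant_voxels_rate"].iloc[1:] == 0).all()

    def test_linear_growth_constant_rate(self):
        from phenovox.phenotypes import PhenotypeRecord

        recs = [
            PhenotypeRecord(plant_id="p", day=d, plant_voxels=100 + 10 * d)
            for d in range(5)
        ]
        df = trajectory(recs)
        assert (df["plant_voxels_rate"].iloc[1:] == 10).all()

    def test_growing_plant_positive_bc_volume_rate(self):
        from phenovox import synthetic as syn
        from tests.conftest import SMALL_SPEC

        models = syn.make_timeseries(SMALL_SPEC, n_days=3, day_scale=1.1)
        recs = []
        for m in models:
            cloud = to_plant_cloud(m.grid)
            rec = compute_phenotypes(cloud, day=m.truth.day)
            recs.append(rec)
        df = trajectory(recs)
        assert (df["bc_volume_rate"].iloc[1:] > 0).all()
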