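"""Parametric maize-like synthetic plants with exact ground truth.

The generator builds a labelled voxel model of a maize-like shoot — one
near-vertical tapered stem, alternate-phyllotaxy ribbon leaves attached
one per node, and a dense ellipsoidal top-leaf-cluster (TLC) capping the
stem — and renders it to binary silhouettes and simple RGB scenes with
pinhole cameras on a horizontal ring.  Every voxel carries a component
label and the truth record stores exact counts and analytic leaf arc
lengths, so each pipeline stage can be tested against ground truth with
no external image data.

Leaf geometry: each leaf midline is a planar parabola in the vertical
plane of its azimuth,

    z(d) = node + a*d - (a/D)*d^2,   d in [0, D],

(takeoff slope ``a``, horizontal run ``D``), swept into a ribbon of
fixed width and thickness.  Its arc length has the closed form
``L = D * G(a) / a`` with ``G(a) = (a*sqrt(1+a^2) + asinh(a)) / 2``, so
``D`` is chosen from the requested arc length and the stored truth
length is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree
from skimage.color import hsv2rgb
from skimage.morphology import dilation, disk

from phenovox.cameras import CameraView, make_turntable_cameras, project
from phenovox.carving import VoxelGrid
from phenovox.phenotypes import PhenotypeRecord
from phenovox.segmentation import Silhouette

__all__ = [
    "SyntheticPlantSpec",
    "LabeledModel",
    "make_plant",
    "random_spec",
    "default_cameras",
    "render_silhouette",
    "render_scene",
    "make_timeseries",
]

STEM_LABEL = 0
TLC_LABEL = 1
FIRST_LEAF_LABEL = 2


def _parabola_gauge(a: float) -> float:
    """G(a) such that the leaf arc length is D * G(a) / a."""
    return (a * math.sqrt(1.0 + a * a) + math.asinh(a)) / 2.0


@dataclass(frozen=True)
class SyntheticPlantSpec:
    """Parameters of one synthetic plant (all geometry in voxel units).

    Defaults model a late-vegetative maize shoot on a 192 x 192 x 256
    grid: five full-grown leaves below a dense TLC, alternate 0/180
    degree phyllotaxy with azimuth jitter, and arc lengths decreasing
    with emergence order.  ``clearance_min`` is the smallest allowed
    gap between distinct leaves (and between leaves and the TLC); the
    default is twice the leaf-clustering ``min_distance`` so cluster
    recovery is guaranteed by construction.
    """

    seed: int = 0
    grid_dims: tuple[int, int, int] = (192, 192, 256)
    edge: float = 1.0
    stem_height: float = 190.0
    stem_radius_base: float = 4.0
    stem_radius_top: float = 2.5
    n_leaves: int = 5
    node_heights: tuple[float, ...] | None = None
    leaf_arc_lengths: tuple[float, ...] | None = None
    takeoff_slope: float = 0.6
    leaf_width: float = 5.0
    leaf_thickness: float = 2.0
    tlc_radius: float = 14.0
    tlc_height: float = 12.0
    jitter_deg: float = 10.0
    clearance_min: float = 4.0
    day_scale: float = 1.1

    def resolved_nodes(self) -> tuple[float, ...]:
        if self.node_heights is not None:
            nodes = tuple(float(h) for h in self.node_heights)
        elif self.n_leaves == 0:
            nodes = ()
        else:
            lo, hi = 0.29 * self.stem_height, 0.82 * self.stem_height
            nodes = tuple(np.linspace(lo, hi, self.n_leaves))
        if len(nodes) != self.n_leaves:
            raise ValueError("n_leaves must equal len(node_heights)")
        if any(h >= self.stem_height for h in nodes):
            raise ValueError("node heights must lie below stem_height")
        if list(nodes) != sorted(set(nodes)):
            raise ValueError("node heights must be strictly increasing")
        return nodes

    def resolved_arcs(self) -> tuple[float, ...]:
        if self.leaf_arc_lengths is not None:
            arcs = tuple(float(a) for a in self.leaf_arc_lengths)
        elif self.n_leaves == 0:
            arcs = ()
        else:
            # First-emerged (lowest) leaf is the longest.
            arcs = tuple(np.linspace(85.0, 50.0, self.n_leaves))
        if len(arcs) != self.n_leaves:
            raise ValueError("n_leaves must equal len(leaf_arc_lengths)")
        if any(a <= 0 for a in arcs):
            raise ValueError("leaf arc lengths must be positive")
        return arcs

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "grid_dims": list(self.grid_dims),
            "edge": self.edge,
            "stem_height": self.stem_height,
            "stem_radius_base": self.stem_radius_base,
            "stem_radius_top": self.stem_radius_top,
            "n_leaves": self.n_leaves,
            "node_heights": None
            if self.node_heights is None
            else list(self.node_heights),
            "leaf_arc_lengths": None
            if self.leaf_arc_lengths is None
            else list(self.leaf_arc_lengths),
            "takeoff_slope": self.takeoff_slope,
            "leaf_width": self.leaf_width,
            "leaf_thickness": self.leaf_thickness,
            "tlc_radius": self.tlc_radius,
            "tlc_height": self.tlc_height,
            "jitter_deg": self.jitter_deg,
            "clearance_min": self.clearance_min,
            "day_scale": self.day_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticPlantSpec":
        d = dict(d)
        for key in ("grid_dims", "node_heights", "leaf_arc_lengths"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class LabeledModel:
    """A synthetic plant: occupancy grid, per-voxel labels, exact truth.

    ``labels`` matches the grid shape: -1 empty, 0 stem, 1 TLC, 2+i for
    leaf i (emergence order).  ``truth`` holds counts recomputable from
    the labels plus the analytic per-leaf arc lengths.
    """

    grid: VoxelGrid
    labels: np.ndarray
    truth: PhenotypeRecord
    spec: SyntheticPlantSpec

    def component_points(self, label: int) -> np.ndarray:
        return np.argwhere(self.labels == label)


def _stem_radius(spec: SyntheticPlantSpec, z: np.ndarray) -> np.ndarray:
    frac = np.clip(z / max(spec.stem_height, 1e-9), 0.0, 1.0)
    return spec.stem_radius_base + (spec.stem_radius_top - spec.stem_radius_base) * frac


def _leaf_voxels(
    spec: SyntheticPlantSpec,
    node_z: float,
    azimuth_rad: float,
    arc_length: float,
) -> tuple[np.ndarray, float]:
    """Voxelize one ribbon leaf; returns (indices, horizontal run D)."""
    a = spec.takeoff_slope
    D = arc_length * a / _parabola_gauge(a)
    b = a / D
    cx, cy = spec.grid_dims[0] / 2.0, spec.grid_dims[1] / 2.0
    ux, uy = math.cos(azimuth_rad), math.sin(azimuth_rad)
    s0 = float(_stem_radius(spec, np.array([node_z]))[0]) - 0.5
    wdir = np.array([-uy, ux, 0.0])

    ds = 0.25
    d = np.arange(0.0, D + ds, ds)
    slope = a - 2.0 * b * d
    tangent = np.stack(
        [np.full_like(d, ux), np.full_like(d, uy), slope], axis=1
    )
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    normal = np.cross(tangent, wdir)  # in-plane thickness direction

    centers = np.stack(
        [
            cx + ux * (s0 + d),
            cy + uy * (s0 + d),
            node_z + a * d - b * d * d,
        ],
        axis=1,
    )
    half_w = spec.leaf_width / 2.0
    half_t = spec.leaf_thickness / 2.0
    alphas = np.arange(-half_w, half_w + 1e-9, 0.4)
    betas = np.arange(-half_t, half_t + 1e-9, 0.4)
    pts = (
        centers[:, None, None, :]
        + alphas[None, :, None, None] * wdir[None, None, None, :]
        + betas[None, None, :, None] * normal[:, None, None, :]
    ).reshape(-1, 3)
    idx = np.unique(np.floor(pts).astype(np.int64), axis=0)
    dims = spec.grid_dims
    ok = (
        (idx[:, 0] >= 0)
        & (idx[:, 0] < dims[0])
        & (idx[:, 1] >= 0)
        & (idx[:, 1] < dims[1])
        & (idx[:, 2] >= 0)
        & (idx[:, 2] < dims[2])
    )
    if not ok.all():
        raise ValueError("leaf extends outside the grid; shrink arc length")
    return idx, D


def make_plant(spec: SyntheticPlantSpec) -> LabeledModel:
    """Build the labelled voxel model for one plant (deterministic by seed).

    Leaves violating the pairwise clearance minimum trigger regeneration
    with fresh azimuth jitter, up to 10 attempts.
    """
    dims = spec.grid_dims
    M, N, H = dims
    if spec.stem_height >= H:
        raise ValueError("stem_height must fit inside the grid")
    nodes = spec.resolved_nodes()
    arcs = spec.resolved_arcs()
    rng = np.random.default_rng(spec.seed)

    labels = np.full(dims, -1, dtype=np.int16)

    # Stem: vertical tapered solid of revolution around the grid centre.
    cx, cy = M / 2.0, N / 2.0
    n_layers = int(math.ceil(spec.stem_height))
    ii, jj = np.meshgrid(np.arange(M), np.arange(N), indexing="ij")
    rho2 = (ii + 0.5 - cx) ** 2 + (jj + 0.5 - cy) ** 2
    tlc_zmin = (
        int(math.floor(spec.stem_height - spec.tlc_height))
        if spec.tlc_radius > 0 and spec.tlc_height > 0
        else n_layers
    )
    for k in range(n_layers):
        r = float(_stem_radius(spec, np.array([k + 0.5]))[0])
        layer = rho2 <= r * r
        labels[:, :, k][layer] = STEM_LABEL if k < tlc_zmin else TLC_LABEL

    # TLC: dense ellipsoidal cluster capping the stem.
    if spec.tlc_radius > 0 and spec.tlc_height > 0:
        z0 = spec.stem_height
        k_lo = max(0, int(math.floor(z0 - spec.tlc_height)))
        k_hi = min(H - 1, int(math.ceil(z0 + spec.tlc_height)))
        for k in range(k_lo, k_hi + 1):
            dz = (k + 0.5 - z0) / spec.tlc_height
            if abs(dz) > 1.0:
                continue
            r = spec.tlc_radius * math.sqrt(max(0.0, 1.0 - dz * dz))
            layer = rho2 <= r * r
            labels[:, :, k][layer] = TLC_LABEL

    # Leaves: alternate-phyllotaxy ribbons, one per node, clearance-checked.
    leaf_sets: list[np.ndarray] = []
    for attempt in range(10):
        trial = np.full(dims, -1, dtype=np.int16)
        leaf_sets = []
        ok = True
        for li, (node_z, arc) in enumerate(zip(nodes, arcs)):
            az = math.radians(
                180.0 * (li % 2) + rng.uniform(-spec.jitter_deg, spec.jitter_deg)
            )
            idx, _ = _leaf_voxels(spec, node_z, az, arc)
            # Voxels already claimed by the stem/TLC stay stem/TLC.
            free = labels[idx[:, 0], idx[:, 1], idx[:, 2]] == -1
            idx = idx[free]
            if trial[idx[:, 0], idx[:, 1], idx[:, 2]].max(initial=-1) != -1:
                ok = False
                break
            trial[idx[:, 0], idx[:, 1], idx[:, 2]] = FIRST_LEAF_LABEL + li
            leaf_sets.append(idx)
        if ok and len(leaf_sets) > 1:
            trees = [cKDTree(s.astype(float)) for s in leaf_sets]
            for i in range(len(leaf_sets)):
                for j in range(i + 1, len(leaf_sets)):
                    d = trees[i].query(leaf_sets[j].astype(float), k=1)[0].min()
                    if d < spec.clearance_min:
                        ok = False
                        break
                if not ok:
                    break
        if ok and leaf_sets and spec.tlc_radius > 0:
            tlc_pts = np.argwhere(labels == TLC_LABEL).astype(float)
            if len(tlc_pts):
                ttree = cKDTree(tlc_pts)
                for s in leaf_sets:
                    if ttree.query(s.astype(float), k=1)[0].min() < spec.clearance_min:
                        ok = False
                        break
        if ok:
            for li, idx in enumerate(leaf_sets):
                labels[idx[:, 0], idx[:, 1], idx[:, 2]] = FIRST_LEAF_LABEL + li
            break
    else:
        raise ValueError(
            "could not place leaves with the required clearance in 10 attempts"
        )

    occupancy = labels >= 0
    origin = np.array([-M / 2.0, -N / 2.0, 0.0]) * spec.edge
    grid = VoxelGrid(dims=dims, origin=origin, edge=spec.edge, occupancy=occupancy)

    stem_ks = np.argwhere(labels == STEM_LABEL)
    truth = PhenotypeRecord(
        plant_id=f"synthetic-{spec.seed}",
        edge=spec.edge,
        plant_voxels=int(occupancy.sum()),
        leaf_count=spec.n_leaves,
        leaf_lengths=[a * spec.edge for a in arcs],
        leaf_volumes=[int(len(s)) for s in leaf_sets],
        total_leaf_volume=int(sum(len(s) for s in leaf_sets)),
        tlc_volume=int((labels == TLC_LABEL).sum()),
        tlc_base=tlc_zmin,
        stem_volume=int(len(stem_ks)),
        stem_height=float(stem_ks[:, 2].max() - stem_ks[:, 2].min())
        if len(stem_ks)
        else math.nan,
    )
    return LabeledModel(grid=grid, labels=labels, truth=truth, spec=spec)


def random_spec(
    seed: int, grid_dims: tuple[int, int, int] = (192, 192, 256)
) -> SyntheticPlantSpec:
    """Draw a clearance-compliant random plant spec for randomized suites."""
    rng = np.random.default_rng(seed)
    n_leaves = int(rng.integers(4, 7))
    stem_height = float(rng.uniform(0.68, 0.78)) * grid_dims[2]
    lo = stem_height * rng.uniform(0.26, 0.32)
    hi = stem_height * rng.uniform(0.78, 0.84)
    nodes = np.linspace(lo, hi, n_leaves)
    nodes = nodes + rng.uniform(-2.0, 2.0, size=n_leaves)
    max_arc = 0.42 * grid_dims[0]
    arcs = np.linspace(max_arc, 0.6 * max_arc, n_leaves) * rng.uniform(
        0.95, 1.05, size=n_leaves
    )
    return SyntheticPlantSpec(
        seed=seed,
        grid_dims=grid_dims,
        stem_height=stem_height,
        stem_radius_base=float(rng.uniform(3.6, 4.5)),
        stem_radius_top=float(rng.uniform(2.2, 2.9)),
        n_leaves=n_leaves,
        node_heights=tuple(sorted(float(h) for h in nodes)),
        leaf_arc_lengths=tuple(float(a) for a in arcs),
        takeoff_slope=float(rng.uniform(0.55, 0.7)),
        leaf_width=float(rng.uniform(4.5, 5.5)),
        tlc_radius=float(rng.uniform(12.0, 15.0)),
        tlc_height=float(rng.uniform(10.0, 13.0)),
        jitter_deg=float(rng.uniform(6.0, 14.0)),
    )


def default_cameras(
    model: LabeledModel,
    n_views: int = 10,
    image_size: tuple[int, int] = (1280, 1280),
    focal: float = 1600.0,
) -> list[CameraView]:
    """Camera ring matching the model's grid (aimed at the grid centre)."""
    dims = model.grid.dims
    edge = model.grid.edge
    radius = 4.0 * max(dims) * edge
    height = dims[2] * edge / 2.0
    return make_turntable_cameras(
        n_views,
        radius=radius,
        height=height,
        focal=focal,
        image_size=image_size,
        target=(0.0, 0.0, height),
    )


def pixels_per_voxel(model: LabeledModel, cam: CameraView) -> float:
    """Approximate image-plane footprint (px) of one voxel edge."""
    dims = model.grid.dims
    center = model.grid.origin + 0.5 * np.array(dims) * model.grid.edge
    dist = float(np.linalg.norm(center - cam.center))
    return cam.focal[0] * model.grid.edge / max(dist, 1e-9)


def render_silhouette(
    model: LabeledModel, cam: CameraView, dilation_radius: int = 1
) -> Silhouette:
    """Binary silhouette: splat projected voxel centres, close cracks.

    Every occupied voxel's centre is projected, rounded to its nearest
    pixel and set, then a ``dilation_radius``-pixel dilation closes
    sampling cracks; the carver's centre-projection lookup therefore
    retains every model voxel (visual-hull superset by construction).
    When one voxel spans more than ~2 pixels the 1-pixel default leaves
    cracks between splats; pass a radius of about
    ``ceil(0.55 * pixels_per_voxel)`` for a solid silhouette.
    """
    w, h = cam.image_size
    mask = np.zeros((h, w), dtype=bool)
    idx = model.grid.occupied_indices()
    if len(idx):
        uv, in_front = project(model.grid.centers(idx), cam)
        uv = uv[in_front]
        u = np.rint(uv[:, 0]).astype(np.int64)
        v = np.rint(uv[:, 1]).astype(np.int64)
        ok = (u >= 0) & (u < w) & (v >= 0) & (v < h)
        mask[v[ok], u[ok]] = True
        mask = dilation(mask, disk(max(1, int(dilation_radius))))
    return Silhouette(mask=mask, view_id=cam.view_id)


def render_scene(
    model: LabeledModel,
    cam: CameraView,
    noise_sigma: float = 0.0,
    brightness_offset: float = 0.0,
    plant_hsv: tuple[float, float, float] = (0.33, 0.65, 0.55),
    background_gray: float = 0.45,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simple RGB scene + plant-free background frame + truth mask.

    The plant is painted in one HSV colour (default inside the standard
    green band) on a homogeneous gray background, with optional Gaussian
    pixel noise and a brightness offset applied to the plant frame only
    (emulating lighting drift between background and plant captures).
    Returns ``(image, background, truth_mask)`` as floats in [0, 1].
    The plant region is rendered solid (splat dilation scaled to the
    voxel footprint) so the scene behaves like a real photographed
    plant rather than a point cloud.
    """
    dil = max(1, math.ceil(0.55 * pixels_per_voxel(model, cam)))
    sil = render_silhouette(model, cam, dilation_radius=dil)
    h, w = sil.mask.shape
    background = np.full((h, w, 3), background_gray, dtype=float)
    image = background.copy()
    plant_rgb = hsv2rgb(np.array(plant_hsv, dtype=float).reshape(1, 1, 3)).reshape(3)
    image[sil.mask] = plant_rgb
    image = image + brightness_offset
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_sigma, size=image.shape)
        background = background + rng.normal(0.0, noise_sigma, size=background.shape)
    return (
        np.clip(image, 0.0, 1.0),
        np.clip(background, 0.0, 1.0),
        sil.mask.copy(),
    )


def make_timeseries(
    spec: SyntheticPlantSpec, n_days: int, day_scale: float | None = None
) -> list[LabeledModel]:
    """Per-day growth series: day d is the base plant scaled by scale^d.

    Stem height, radii, node heights, arc lengths and TLC axes all grow
    multiplicatively; the seed (hence azimuth jitter) is shared across
    days of one plant so the architecture stays coherent.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    s = spec.day_scale if day_scale is None else day_scale
    models = []
    nodes0 = spec.resolved_nodes()
    arcs0 = spec.resolved_arcs()
    for d in range(n_days):
        f = s**d
        day_spec = replace(
            spec,
            stem_height=spec.stem_height * f,
            stem_radius_base=spec.stem_radius_base * f,
            stem_radius_top=spec.stem_radius_top * f,
            node_heights=tuple(h * f for h in nodes0),
            leaf_arc_lengths=tuple(a * f for a in arcs0),
            tlc_radius=spec.tlc_radius * f,
            tlc_height=spec.tlc_height * f,
        )
        model = make_plant(day_spec)
        model.truth.day = d
        models.append(model)
    return models
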