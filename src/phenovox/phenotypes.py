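"""Holistic and component 3D phenotypes.

Holistic phenotypes treat the plant as one object: voxel count (plant
volume), convex-hull volume and volumetric occupancy ratio, minimum
enclosing sphere volume, axis-aligned bounding-cuboid extents with the
primary/secondary aspect ratios

    PAR_p = Height_BC / Width_BC,   PAR_s = Height_BC / Depth_BC,

(width = longer horizontal extent, depth = shorter), and the volume of
the minimum bounding cuboid with its vertical axis fixed (minimum-area
oriented rectangle of the xy-projection times the z-extent).

Component phenotypes require the stem/leaf/TLC partition: leaf count,
per-leaf volume and 3D leaf length (via skeletonization), TLC volume,
stem height S_h = z_max - z_min, stem volume, mean stem cross-section
area and the circularity-height profile (per-layer cross-section area
and its rate of change with height, a lodging-susceptibility proxy).

All volumes are voxel counts / voxel-units^3 (the physical value is
count * edge^3 mm^3); lengths are reported in both voxel units and mm.
Geometric volumes (hull, sphere, cuboids) are computed on voxel centres
without half-voxel inflation so ratios are reproducible bit-for-bit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from phenovox.carving import PlantCloud
from phenovox.geometry import min_enclosing_sphere, min_oriented_rectangle_area
from phenovox.separation import PlantComponents
from phenovox.skeleton import ContractionParams, arc_length, fit_leaf_curve, laplacian_contract

__all__ = [
    "PhenotypeRecord",
    "plant_volume",
    "convex_hull_volume",
    "occupancy_ratio",
    "min_enclosing_sphere_volume",
    "bounding_cuboid",
    "aspect_ratios",
    "min_bounding_cuboid_volume",
    "stem_phenotypes",
    "compute_phenotypes",
    "trajectory",
]


@dataclass
class PhenotypeRecord:
    """All holistic and component measurements for one plant on one day.

    Volumes are voxel counts or voxel-units^3; ``edge`` (mm) converts to
    physical units.  Missing/undefined values are NaN.
    """

    plant_id: str = ""
    day: int = 0
    edge: float = 1.0
    plant_voxels: int = 0
    convexhull_volume: float = math.nan
    occupancy_ratio: float = math.nan
    sphere_volume: float = math.nan
    bc_height: float = math.nan
    bc_width: float = math.nan
    bc_depth: float = math.nan
    bc_volume: float = math.nan
    mbc_volume: float = math.nan
    par_primary: float = math.nan
    par_secondary: float = math.nan
    leaf_count: int = 0
    leaf_lengths: list[float] = field(default_factory=list)
    leaf_volumes: list[int] = field(default_factory=list)
    total_leaf_volume: int = 0
    tlc_volume: int = 0
    tlc_base: int = -1
    stem_height: float = math.nan
    stem_volume: int = 0
    mean_stem_cs_area: float = math.nan
    circularity_profile: list[tuple[int, int]] = field(default_factory=list)
    circularity_rate: list[tuple[int, int]] = field(default_factory=list)
    debris_volume: int = 0

    SCALAR_COLUMNS = (
        "plant_id",
        "day",
        "edge",
        "plant_voxels",
        "convexhull_volume",
        "occupancy_ratio",
        "sphere_volume",
        "bc_height",
        "bc_width",
        "bc_depth",
        "bc_volume",
        "mbc_volume",
        "par_primary",
        "par_secondary",
        "leaf_count",
        "total_leaf_volume",
        "tlc_volume",
        "tlc_base",
        "stem_height",
        "stem_volume",
        "mean_stem_cs_area",
        "debris_volume",
    )

    def to_flat_dict(self) -> dict:
        """One fixed-order CSV row; lengths also converted to mm."""
        d = {k: getattr(self, k) for k in self.SCALAR_COLUMNS}
        d["stem_height_mm"] = self.stem_height * self.edge
        d["median_leaf_length_mm"] = (
            float(np.median(self.leaf_lengths)) if self.leaf_lengths else math.nan
        )
        return d

    def leaf_table(self) -> pd.DataFrame:
        """Per-leaf table: emergence-ordered index, volume, length."""
        return pd.DataFrame(
            {
                "leaf": np.arange(len(self.leaf_volumes)),
                "volume_voxels": self.leaf_volumes,
                "length_voxel_units": [
                    l / self.edge if np.isfinite(l) else math.nan
                    for l in self.leaf_lengths
                ],
                "length_mm": self.leaf_lengths,
            }
        )


def _points_of(P: PlantCloud | np.ndarray) -> np.ndarray:
    if isinstance(P, PlantCloud):
        return P.points.astype(float)
    return np.asarray(P, dtype=float).reshape(-1, 3)


def plant_volume(P: PlantCloud | np.ndarray) -> int:
    """Number of voxels in the reconstructed plant."""
    return len(_points_of(P))


def convex_hull_volume(P: PlantCloud | np.ndarray) -> float:
    """Volume of the 3D convex hull of voxel centres (voxel-units^3).

    NaN for degenerate (fewer than 4 non-coplanar points) clouds.
    """
    pts = _points_of(P)
    if len(pts) < 4:
        return math.nan
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        return math.nan


def occupancy_ratio(P: PlantCloud | np.ndarray) -> float:
    """Plant voxel count over convex-hull volume (dimensionless)."""
    hv = convex_hull_volume(P)
    if not np.isfinite(hv) or hv <= 0:
        return math.nan
    return plant_volume(P) / hv


def min_enclosing_sphere_volume(P: PlantCloud | np.ndarray) -> float:
    """Volume (4/3)*pi*r^3 of the exact minimum enclosing sphere."""
    pts = _points_of(P)
    _, r = min_enclosing_sphere(pts)
    return 4.0 / 3.0 * math.pi * r**3


def bounding_cuboid(P: PlantCloud | np.ndarray) -> tuple[float, float, float]:
    """Axis-aligned extents (height, width, depth) in voxel units.

    Height is the z extent; width the longer and depth the shorter of
    the two horizontal extents (by magnitude, not axis identity).
    """
    pts = _points_of(P)
    if len(pts) == 0:
        raise ValueError("empty point set")
    ext = pts.max(axis=0) - pts.min(axis=0)
    height = float(ext[2])
    width = float(max(ext[0], ext[1]))
    depth = float(min(ext[0], ext[1]))
    return height, width, depth


def aspect_ratios(height: float, width: float, depth: float) -> tuple[float, float]:
    """Primary and secondary aspect ratios (height/width, height/depth)."""
    par_p = height / width if width > 0 else math.nan
    par_s = height / depth if depth > 0 else math.nan
    return par_p, par_s


def min_bounding_cuboid_volume(P: PlantCloud | np.ndarray) -> float:
    """Minimum-volume bounding cuboid with one axis fixed vertical.

    Minimum-area oriented rectangle of the xy-projection times the z
    extent (plants are gravity-aligned, so the box is only free to
    rotate about z).
    """
    pts = _points_of(P)
    if len(pts) == 0:
        raise ValueError("empty point set")
    area = min_oriented_rectangle_area(pts[:, :2])
    return area * float(pts[:, 2].max() - pts[:, 2].min())


def stem_phenotypes(
    S: np.ndarray,
) -> tuple[float, int, float, list[tuple[int, int]], list[tuple[int, int]]]:
    """Stem measurements from the stem voxel set.

    Returns ``(stem_height, stem_volume, mean_cs_area, profile, rate)``
    with S_h = z_max - z_min in voxel units, per-layer cross-section
    areas (the circularity-height profile, heights strictly increasing)
    and their first differences (rate of change with height).
    """
    S = np.asarray(S).reshape(-1, 3)
    if len(S) == 0:
        return math.nan, 0, math.nan, [], []
    ks = S[:, 2]
    s_h = float(ks.max() - ks.min())
    uniq, counts = np.unique(ks, return_counts=True)
    profile = [(int(k), int(c)) for k, c in zip(uniq, counts)]
    rate = [
        (int(uniq[i + 1]), int(counts[i + 1] - counts[i]))
        for i in range(len(uniq) - 1)
    ]
    return s_h, int(len(S)), float(counts.mean()), profile, rate


def compute_phenotypes(
    P: PlantCloud,
    components: PlantComponents | None = None,
    plant_id: str = "",
    day: int = 0,
    contraction: ContractionParams | None = None,
    poly_order: int = 4,
) -> PhenotypeRecord:
    """Fill a :class:`PhenotypeRecord` from a plant cloud and its partition.

    Holistic phenotypes need only the cloud; component phenotypes are
    filled when ``components`` is given.  Leaves too small to
    skeletonize get NaN length (with a warning) rather than aborting the
    record.  The partition conservation invariant is asserted.
    """
    rec = PhenotypeRecord(plant_id=plant_id, day=day, edge=P.edge)
    pts = P.points.astype(float)
    rec.plant_voxels = len(pts)
    if rec.plant_voxels == 0:
        return rec
    rec.convexhull_volume = convex_hull_volume(P)
    rec.occupancy_ratio = occupancy_ratio(P)
    rec.sphere_volume = min_enclosing_sphere_volume(P)
    h, w, d = bounding_cuboid(P)
    rec.bc_height, rec.bc_width, rec.bc_depth = h, w, d
    rec.bc_volume = h * w * d
    rec.mbc_volume = min_bounding_cuboid_volume(P)
    rec.par_primary, rec.par_secondary = aspect_ratios(h, w, d)

    if components is None:
        return rec

    contraction = contraction or ContractionParams()
    (
        rec.stem_height,
        rec.stem_volume,
        rec.mean_stem_cs_area,
        rec.circularity_profile,
        rec.circularity_rate,
    ) = stem_phenotypes(components.stem)
    rec.tlc_volume = len(components.tlc)
    rec.tlc_base = components.tlc_base
    rec.leaf_count = len(components.leaves)
    rec.leaf_volumes = [len(l) for l in components.leaves]
    rec.total_leaf_volume = int(sum(rec.leaf_volumes))
    rec.debris_volume = len(components.debris)
    lengths = []
    for i, leaf in enumerate(components.leaves):
        try:
            contracted = laplacian_contract(leaf.astype(float), contraction)
            skel = fit_leaf_curve(contracted, order=poly_order)
            lengths.append(arc_length(skel, edge=P.edge))
        except ValueError as exc:
            warnings.warn(f"leaf {i}: length not measurable ({exc})", stacklevel=2)
            lengths.append(math.nan)
    rec.leaf_lengths = lengths

    conserved = (
        rec.stem_volume + rec.tlc_volume + rec.total_leaf_volume + rec.debris_volume
    )
    if conserved != rec.plant_voxels:
        raise AssertionError(
            f"partition broken: {conserved} component voxels vs {rec.plant_voxels} plant voxels"
        )
    return rec


def trajectory(records: list[PhenotypeRecord]) -> pd.DataFrame:
    """Per-day phenotype series with growth rates (first differences).

    Records are sorted by day; every scalar numeric phenotype gets a
    ``<name>_rate`` column holding its day-over-day difference (NaN on
    the first day).  No smoothing is applied.
    """
    if not records:
        raise ValueError("no records")
    rows = [r.to_flat_dict() for r in sorted(records, key=lambda r: r.day)]
    df = pd.DataFrame(rows)
    numeric = [
        c
        for c in df.columns
        if c not in ("plant_id", "day", "edge") and pd.api.types.is_numeric_dtype(df[c])
    ]
    for c in numeric:
        df[c + "_rate"] = df[c].diff()
    return df
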