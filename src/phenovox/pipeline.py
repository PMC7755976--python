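"""End-to-end pipeline orchestration.

``run_pipeline`` chains the stages — per-view segmentation, space
carving, largest-component filtering, organ separation, phenotype
computation — and persists every intermediate as a file (masks, PLY
clouds, CSV/JSON reports, a plain-text run log), so each stage is also
independently runnable and re-runs are bit-reproducible for all
non-image outputs.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from phenovox.cameras import CameraView, read_cameras
from phenovox.carving import (
    PlantCloud,
    VoxelGrid,
    carve,
    init_grid,
    largest_component,
    to_plant_cloud,
)
from phenovox.io import (
    cloud_to_ply,
    components_to_ply,
    read_image,
    read_mask,
    write_json,
    write_mask,
    write_ply,
)
from phenovox.phenotypes import PhenotypeRecord, compute_phenotypes
from phenovox.segmentation import SegmentationConfig, Silhouette, segment_view
from phenovox.separation import SeparationParams, separate
from phenovox.skeleton import ContractionParams, fit_leaf_curve, laplacian_contract, skeleton_polyline

__all__ = ["PipelineConfig", "run_pipeline", "reconstruct_from_masks"]


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, serialized with results for provenance.

    ``grid_bounds`` is ``((xmin, ymin, zmin), (xmax, ymax, zmax))`` in mm
    and must divide into cubic voxels at ``grid_resolution``.
    """

    grid_bounds: tuple = ((-128.0, -128.0, 0.0), (128.0, 128.0, 256.0))
    grid_resolution: tuple[int, int, int] = (256, 256, 256)
    footprint: str = "center"
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    separation: SeparationParams = field(default_factory=SeparationParams)
    contraction: ContractionParams = field(default_factory=ContractionParams)
    poly_order: int = 4
    component_filter: bool = True

    def to_dict(self) -> dict:
        return {
            "grid_bounds": [list(self.grid_bounds[0]), list(self.grid_bounds[1])],
            "grid_resolution": list(self.grid_resolution),
            "footprint": self.footprint,
            "segmentation": self.segmentation.to_dict(),
            "separation": self.separation.to_dict(),
            "contraction": self.contraction.to_dict(),
            "poly_order": self.poly_order,
            "component_filter": self.component_filter,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "grid_bounds" in d:
            d["grid_bounds"] = (tuple(d["grid_bounds"][0]), tuple(d["grid_bounds"][1]))
        if "grid_resolution" in d:
            d["grid_resolution"] = tuple(d["grid_resolution"])
        if "segmentation" in d:
            d["segmentation"] = SegmentationConfig.from_dict(d["segmentation"])
        if "separation" in d:
            d["separation"] = SeparationParams.from_dict(d["separation"])
        if "contraction" in d:
            d["contraction"] = ContractionParams.from_dict(d["contraction"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _match_views(
    cams: list[CameraView], image_dir: Path, background_dir: Path
) -> list[tuple[CameraView, Path, Path]]:
    triples = []
    missing = []
    for cam in cams:
        img = image_dir / f"{cam.view_id}.png"
        bg = background_dir / f"{cam.view_id}.png"
        if not img.exists() or not bg.exists():
            missing.append(cam.view_id)
        else:
            triples.append((cam, img, bg))
    if missing:
        raise FileNotFoundError(
            "missing image/background for view(s): " + ", ".join(missing)
        )
    return triples


def reconstruct_from_masks(
    masks: list[Silhouette], cams: list[CameraView], config: PipelineConfig
) -> PlantCloud:
    """Carve the voxel grid from ready-made silhouettes."""
    by_id = {c.view_id: c for c in cams}
    views = []
    unmatched = [s.view_id for s in masks if s.view_id not in by_id]
    if unmatched:
        raise KeyError("no camera for view(s): " + ", ".join(unmatched))
    for sil in masks:
        views.append((sil, by_id[sil.view_id]))
    grid = init_grid(config.grid_bounds, config.grid_resolution)
    carved = carve(grid, views, footprint=config.footprint)
    cloud = to_plant_cloud(carved)
    if config.component_filter:
        cloud = largest_component(cloud)
    return cloud


def run_pipeline(
    image_dir: str | Path,
    background_dir: str | Path,
    camera_file: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path = "phenovox_out",
    plant_id: str = "plant",
    day: int = 0,
) -> tuple[PhenotypeRecord, dict]:
    """Segment -> carve -> separate -> measure, writing all artifacts.

    Images and backgrounds are matched to cameras by filename
    ``<view_id>.png``.  Returns the phenotype record and a dict of
    artifact paths.  Raises on any stage error (no partial CSV/JSON
    outputs are left behind on failure of an earlier stage).
    """
    config = config or PipelineConfig()
    image_dir, background_dir = Path(image_dir), Path(background_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    t0 = time.perf_counter()
    cams = read_cameras(camera_file)
    triples = _match_views(cams, image_dir, background_dir)
    if len(triples) == 1:
        warnings.warn(
            "only one view supplied; the visual hull of a single view is a cone",
            stacklevel=2,
        )
        log("WARNING single view: visual hull is a generalized cone")

    masks = []
    for cam, img_path, bg_path in triples:
        sil = segment_view(
            read_image(img_path), read_image(bg_path), config.segmentation, cam.view_id
        )
        write_mask(out / f"mask_{cam.view_id}.png", sil.mask)
        masks.append(sil)
    log(f"segment: {len(masks)} views in {time.perf_counter() - t0:.2f}s")

    t1 = time.perf_counter()
    cloud = reconstruct_from_masks(masks, cams, config)
    cloud_to_ply(cloud, out / "plant.ply")
    log(f"carve: {len(cloud)} voxels in {time.perf_counter() - t1:.2f}s")

    t2 = time.perf_counter()
    components = separate(cloud, config.separation)
    components_to_ply(components, out / "components.ply")
    sizes = pd.DataFrame(
        [
            {"component": "stem", "voxels": len(components.stem)},
            {"component": "tlc", "voxels": len(components.tlc)},
        ]
        + [
            {"component": f"leaf_{i}", "voxels": len(l)}
            for i, l in enumerate(components.leaves)
        ]
        + [{"component": "debris", "voxels": len(components.debris)}]
    )
    sizes.to_csv(out / "components.csv", index=False)
    log(f"separate: {len(components.leaves)} leaves in {time.perf_counter() - t2:.2f}s")

    t3 = time.perf_counter()
    record = compute_phenotypes(
        cloud,
        components,
        plant_id=plant_id,
        day=day,
        contraction=config.contraction,
        poly_order=config.poly_order,
    )
    # Skeleton polylines for each measurable leaf.
    skel_pts, skel_labels = [], []
    for i, leaf in enumerate(components.leaves):
        try:
            contracted = laplacian_contract(leaf.astype(float), config.contraction)
            skel = fit_leaf_curve(contracted, order=config.poly_order)
            pts = cloud.origin + cloud.edge * (skeleton_polyline(skel) + 0.5)
            skel_pts.append(pts)
            skel_labels.append(np.full(len(pts), 2 + i, dtype=np.int64))
        except ValueError:
            continue
    if skel_pts:
        write_ply(
            out / "skeletons.ply",
            np.concatenate(skel_pts),
            labels=np.concatenate(skel_labels),
        )
    row = record.to_flat_dict()
    pd.DataFrame([row]).to_csv(out / "phenotypes.csv", index=False, float_format="%.9g")
    record.leaf_table().to_csv(out / "leaves.csv", index=False, float_format="%.9g")
    profile = pd.DataFrame(record.circularity_profile, columns=["height", "area"])
    rate = dict(record.circularity_rate)
    profile["area_rate"] = [rate.get(h, np.nan) for h in profile["height"]]
    profile.to_csv(out / "stem_profile.csv", index=False, float_format="%.9g")
    report = {k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in row.items()}
    report["leaf_lengths_mm"] = [
        None if np.isnan(l) else l for l in record.leaf_lengths
    ]
    report["leaf_volumes"] = record.leaf_volumes
    write_json(out / "phenotypes.json", report)
    write_json(out / "config.json", config.to_dict())
    log(f"phenotype: done in {time.perf_counter() - t3:.2f}s")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")

    artifacts = {
        "masks": sorted(str(p) for p in out.glob("mask_*.png")),
        "plant_ply": str(out / "plant.ply"),
        "components_ply": str(out / "components.ply"),
        "components_csv": str(out / "components.csv"),
        "phenotypes_csv": str(out / "phenotypes.csv"),
        "phenotypes_json": str(out / "phenotypes.json"),
        "leaves_csv": str(out / "leaves.csv"),
        "stem_profile_csv": str(out / "stem_profile.csv"),
        "config_json": str(out / "config.json"),
        "log": str(out / "run.log"),
    }
    return record, artifacts
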