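"""File formats tying the pipeline stages together.

Point clouds travel as ASCII PLY (voxel centres in mm, optional integer
component label per vertex: 0 = stem, 1 = TLC, 2.. = leaves in emergence
order, -1 = debris).  Grid metadata (dims, origin, edge) rides along in
PLY comment lines so a cloud read back from disk reconstitutes a full
:class:`~phenovox.carving.PlantCloud`.  Masks are 0/255 PNG; tables are
CSV with fixed column order; configs and reports are JSON.  All writers
are deterministic byte-for-byte for identical inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from phenovox.carving import PlantCloud
from phenovox.separation import PlantComponents

__all__ = [
    "write_ply",
    "read_ply",
    "write_mask",
    "read_mask",
    "read_image",
    "cloud_to_ply",
    "ply_to_cloud",
    "components_to_ply",
    "ply_to_components",
    "write_json",
]

STEM_LABEL = 0
TLC_LABEL = 1
FIRST_LEAF_LABEL = 2
DEBRIS_LABEL = -1


def write_ply(
    path: str | Path,
    points: np.ndarray,
    labels: np.ndarray | None = None,
    comments: list[str] | None = None,
) -> None:
    """Write an ASCII PLY point cloud (optionally with an int label)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    lines = ["ply", "format ascii 1.0"]
    for c in comments or []:
        lines.append(f"comment {c}")
    lines.append(f"element vertex {len(pts)}")
    lines += ["property float x", "property float y", "property float z"]
    if labels is not None:
        labels = np.asarray(labels, dtype=np.int64).reshape(-1)
        if len(labels) != len(pts):
            raise ValueError("labels length must match points")
        lines.append("property int label")
    lines.append("end_header")
    if labels is None:
        lines += [f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}" for p in pts]
    else:
        lines += [
            f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {l}" for p, l in zip(pts, labels)
        ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_ply(
    path: str | Path,
) -> tuple[np.ndarray, np.ndarray | None, list[str]]:
    """Read an ASCII PLY point cloud; returns (points, labels, comments)."""
    text = Path(path).read_text().splitlines()
    if not text or text[0].strip() != "ply":
        raise ValueError(f"{path}: not a PLY file")
    n_vertex = 0
    has_label = False
    comments: list[str] = []
    i = 1
    while i < len(text):
        line = text[i].strip()
        i += 1
        if line.startswith("comment"):
            comments.append(line[len("comment") :].strip())
        elif line.startswith("element vertex"):
            n_vertex = int(line.split()[-1])
        elif line.startswith("property int label"):
            has_label = True
        elif line == "end_header":
            break
    body = text[i : i + n_vertex]
    if len(body) != n_vertex:
        raise ValueError(f"{path}: truncated PLY body")
    if n_vertex == 0:
        return (
            np.empty((0, 3)),
            np.empty(0, dtype=np.int64) if has_label else None,
            comments,
        )
    data = np.array([ln.split() for ln in body], dtype=float)
    pts = data[:, :3]
    labels = data[:, 3].astype(np.int64) if has_label else None
    return pts, labels, comments


def _grid_comments(dims, origin, edge) -> list[str]:
    return [
        f"grid dims {dims[0]} {dims[1]} {dims[2]}",
        f"grid origin {origin[0]:.9g} {origin[1]:.9g} {origin[2]:.9g}",
        f"grid edge {edge:.9g}",
    ]


def _parse_grid_comments(comments: list[str]):
    dims = origin = edge = None
    for c in comments:
        parts = c.split()
        if parts[:2] == ["grid", "dims"]:
            dims = tuple(int(x) for x in parts[2:5])
        elif parts[:2] == ["grid", "origin"]:
            origin = np.array([float(x) for x in parts[2:5]])
        elif parts[:2] == ["grid", "edge"]:
            edge = float(parts[2])
    if dims is None or origin is None or edge is None:
        raise ValueError("PLY lacks grid metadata comments (dims/origin/edge)")
    return dims, origin, edge


def cloud_to_ply(cloud: PlantCloud, path: str | Path) -> None:
    """Export a plant cloud as PLY voxel centres with grid metadata."""
    write_ply(
        path,
        cloud.centers_mm(),
        comments=_grid_comments(cloud.dims, cloud.origin, cloud.edge),
    )


def ply_to_cloud(path: str | Path) -> PlantCloud:
    """Rebuild a PlantCloud (voxel indices) from an exported PLY."""
    pts, _, comments = read_ply(path)
    dims, origin, edge = _parse_grid_comments(comments)
    idx = np.rint((pts - origin) / edge - 0.5).astype(np.int64)
    return PlantCloud(points=idx, dims=dims, origin=origin, edge=edge)


def components_to_ply(components: PlantComponents, path: str | Path) -> None:
    """Export the labelled partition as one PLY (label per vertex)."""
    blocks = [
        (components.stem, STEM_LABEL),
        (components.tlc, TLC_LABEL),
    ]
    blocks += [
        (leaf, FIRST_LEAF_LABEL + i) for i, leaf in enumerate(components.leaves)
    ]
    blocks.append((components.debris, DEBRIS_LABEL))
    pts_list, lab_list = [], []
    for arr, lab in blocks:
        if len(arr):
            pts_list.append(
                components.origin + components.edge * (np.asarray(arr) + 0.5)
            )
            lab_list.append(np.full(len(arr), lab, dtype=np.int64))
    pts = np.concatenate(pts_list) if pts_list else np.empty((0, 3))
    labs = np.concatenate(lab_list) if lab_list else np.empty(0, dtype=np.int64)
    comments = _grid_comments(components.dims, components.origin, components.edge)
    comments.append(f"tlc_base {components.tlc_base}")
    write_ply(path, pts, labels=labs, comments=comments)


def ply_to_components(path: str | Path) -> PlantComponents:
    """Rebuild a PlantComponents partition from a labelled PLY."""
    pts, labels, comments = read_ply(path)
    if labels is None:
        raise ValueError(f"{path}: labelled PLY expected (no label property)")
    dims, origin, edge = _parse_grid_comments(comments)
    tlc_base = -1
    for c in comments:
        if c.startswith("tlc_base"):
            tlc_base = int(c.split()[1])
    idx = np.rint((pts - origin) / edge - 0.5).astype(np.int64)
    leaves = []
    lab = FIRST_LEAF_LABEL
    while np.any(labels == lab):
        leaves.append(idx[labels == lab])
        lab += 1
    return PlantComponents(
        stem=idx[labels == STEM_LABEL],
        tlc=idx[labels == TLC_LABEL],
        leaves=leaves,
        debris=idx[labels == DEBRIS_LABEL],
        tlc_base=tlc_base,
        dims=dims,
        origin=origin,
        edge=edge,
    )


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as 0/255 PNG."""
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def read_image(path: str | Path) -> np.ndarray:
    """Read an RGB image as float in [0, 1]."""
    arr = iio.imread(Path(path))
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    return arr.astype(float)


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a float [0, 1] RGB image as 8-bit PNG."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 255).round().astype(np.uint8))


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
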