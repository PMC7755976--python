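"""Multiview imaging geometry.

A plant is imaged by a ring of calibrated pinhole cameras at known
azimuths on a horizontal circle (equivalently, the plant rotates on a
lifter in front of one fixed camera).  This module models projection of
3D world points into each view — pinhole with skew, two radial and two
tangential lens-distortion coefficients — plus parameter file I/O and a
reprojection-error check used to validate externally supplied
calibrations.

Conventions (shared by every module in the package):

* World frame: right-handed, ``+z`` vertical (up), units millimetres,
  origin at the base centre of the reconstruction volume.  Plant stems
  are assumed roughly aligned with ``+z``.
* Pixel coordinates: ``(u, v) = (column, row)``, origin at the centre of
  the top-left pixel, 0-based.
* Camera frame: ``x`` right, ``y`` down, ``z`` forward (optical axis).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

CAMERA_SCHEMA = "phenovox-cameras-v1"

__all__ = [
    "CameraView",
    "CameraSchemaError",
    "project",
    "undistort_points",
    "backproject",
    "make_turntable_cameras",
    "read_cameras",
    "write_cameras",
    "reprojection_error",
]


class CameraSchemaError(ValueError):
    """A camera parameter file is malformed; the message names the field."""


@dataclass(frozen=True)
class CameraView:
    """Calibrated pinhole camera with lens distortion for one side view.

    Parameters follow the classical photogrammetric model: intrinsics
    ``(fx, fy, cx, cy, skew)``, two radial (``k1, k2``) and two
    tangential (``p1, p2``) distortion coefficients, and a rigid
    world-to-camera transform ``x_cam = R @ x_world + t``.
    """

    view_id: str
    azimuth_deg: float
    focal: tuple[float, float]
    principal_point: tuple[float, float]
    rotation: np.ndarray
    translation: np.ndarray
    image_size: tuple[int, int]
    skew: float = 0.0
    radial_distortion: tuple[float, float] = (0.0, 0.0)
    tangential_distortion: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3):
            raise CameraSchemaError("rotation must be a 3x3 matrix")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise CameraSchemaError("rotation is not orthonormal (field: rotation)")
        if not math.isclose(float(np.linalg.det(R)), 1.0, abs_tol=1e-8):
            raise CameraSchemaError(
                "rotation determinant is not +1 (field: rotation)"
            )
        fx, fy = self.focal
        if not (fx > 0 and fy > 0):
            raise CameraSchemaError("focal lengths must be positive (field: focal)")
        w, h = self.image_size
        if not (w > 0 and h > 0):
            raise CameraSchemaError("image_size components must be positive")
        if not (0.0 <= self.azimuth_deg < 360.0):
            raise CameraSchemaError("azimuth_deg must lie in [0, 360)")

    @property
    def center(self) -> np.ndarray:
        """Camera centre in world coordinates (``-R.T @ t``)."""
        return -self.rotation.T @ self.translation

    def to_dict(self) -> dict:
        return {
            "view_id": self.view_id,
            "azimuth_deg": float(self.azimuth_deg),
            "focal": [float(f) for f in self.focal],
            "principal_point": [float(c) for c in self.principal_point],
            "skew": float(self.skew),
            "radial_distortion": [float(k) for k in self.radial_distortion],
            "tangential_distortion": [float(p) for p in self.tangential_distortion],
            "rotation": np.asarray(self.rotation).tolist(),
            "translation": np.asarray(self.translation).tolist(),
            "image_size": [int(s) for s in self.image_size],
        }


def _distort(x: np.ndarray, y: np.ndarray, cam: CameraView) -> tuple[np.ndarray, np.ndarray]:
    k1, k2 = cam.radial_distortion
    p1, p2 = cam.tangential_distortion
    r2 = x * x + y * y
    radial = 1.0 + k1 * r2 + k2 * r2 * r2
    xd = x * radial + 2.0 * p1 * x * y + p2 * (r2 + 2.0 * x * x)
    yd = y * radial + p1 * (r2 + 2.0 * y * y) + 2.0 * p2 * x * y
    return xd, yd


def project(points: np.ndarray, cam: CameraView) -> tuple[np.ndarray, np.ndarray]:
    """Project world points (mm) into pixel coordinates of one view.

    Pinhole projection with skew, radial ``(k1, k2)`` and tangential
    ``(p1, p2)`` distortion applied in normalized image coordinates.

    Parameters
    ----------
    points : (..., 3) array
        World coordinates in mm.
    cam : CameraView

    Returns
    -------
    uv : (..., 2) array
        Pixel coordinates ``(u, v)``; NaN where the point lies behind
        the camera.
    in_front : (...) bool array
        False flags points at camera-frame depth ``z <= 0``; such points
        are never silently projected.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[-1] != 3:
        raise ValueError("points must have shape (..., 3)")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    cam_pts = pts @ cam.rotation.T + cam.translation
    z = cam_pts[..., 2]
    in_front = z > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        x = cam_pts[..., 0] / z
        y = cam_pts[..., 1] / z
    xd, yd = _distort(x, y, cam)
    fx, fy = cam.focal
    cx, cy = cam.principal_point
    u = fx * xd + cam.skew * yd + cx
    v = fy * yd + cy
    uv = np.stack([u, v], axis=-1)
    uv = np.where(in_front[..., None], uv, np.nan)
    return uv, in_front


def undistort_points(uv: np.ndarray, cam: CameraView, n_iter: int = 25) -> np.ndarray:
    """Invert intrinsics + distortion: pixels -> normalized coordinates.

    Uses fixed-point iteration on the distortion model, accurate to well
    below 1e-8 in normalized units for moderate coefficients
    (|k1|, |k2| <= 0.3).
    """
    uv = np.asarray(uv, dtype=float)
    fx, fy = cam.focal
    cx, cy = cam.principal_point
    yd = (uv[..., 1] - cy) / fy
    xd = (uv[..., 0] - cx - cam.skew * yd) / fx
    x, y = xd.copy(), yd.copy()
    for _ in range(n_iter):
        xe, ye = _distort(x, y, cam)
        x = x - (xe - xd)
        y = y - (ye - yd)
    return np.stack([x, y], axis=-1)


def backproject(uv: np.ndarray, depth: np.ndarray, cam: CameraView) -> np.ndarray:
    """Lift pixels back to world points at known camera-frame depth (mm)."""
    xy = undistort_points(uv, cam)
    depth = np.asarray(depth, dtype=float)
    cam_pts = np.concatenate(
        [xy * depth[..., None], depth[..., None]], axis=-1
    )
    return (cam_pts - cam.translation) @ cam.rotation


def make_turntable_cameras(
    n_views: int,
    radius: float,
    height: float = 0.0,
    focal: float = 1000.0,
    image_size: tuple[int, int] = (800, 800),
    target: Sequence[float] | None = None,
    view_id_prefix: str = "view",
) -> list[CameraView]:
    """Build a ring of cameras equally spaced in azimuth, aimed at one point.

    Cameras sit at ``(radius*cos(az), radius*sin(az), height)`` and all
    look at ``target`` (default the world origin), with the image
    vertical aligned to world ``-z``.  ``n_views=10`` reproduces the
    standard 36-degree-step side-view ring.
    """
    if n_views < 2:
        raise ValueError("n_views must be >= 2")
    if radius <= 0:
        raise ValueError("radius must be positive")
    tgt = np.zeros(3) if target is None else np.asarray(target, dtype=float)
    w, h = image_size
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    up = np.array([0.0, 0.0, 1.0])
    views = []
    for i in range(n_views):
        az = 360.0 * i / n_views
        a = math.radians(az)
        C = np.array([radius * math.cos(a), radius * math.sin(a), height])
        zc = tgt - C
        nz = np.linalg.norm(zc)
        if nz == 0:
            raise ValueError("camera coincides with target")
        zc = zc / nz
        xc = np.cross(zc, up)
        nx = np.linalg.norm(xc)
        if nx < 1e-12:
            raise ValueError("optical axis parallel to the vertical; pick a lower height")
        xc = xc / nx
        yc = np.cross(zc, xc)
        R = np.stack([xc, yc, zc])
        t = -R @ C
        views.append(
            CameraView(
                view_id=f"{view_id_prefix}{i:02d}",
                azimuth_deg=az % 360.0,
                focal=(focal, focal),
                principal_point=(cx, cy),
                rotation=R,
                translation=t,
                image_size=(int(w), int(h)),
            )
        )
    return views


_REQUIRED_FIELDS = (
    "view_id",
    "azimuth_deg",
    "focal",
    "principal_point",
    "skew",
    "radial_distortion",
    "tangential_distortion",
    "rotation",
    "translation",
    "image_size",
)


def write_cameras(views: Sequence[CameraView], path: str | Path) -> None:
    """Write camera parameters as versioned JSON (one object per view)."""
    payload = {"schema": CAMERA_SCHEMA, "views": [v.to_dict() for v in views]}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_cameras(path: str | Path) -> list[CameraView]:
    """Read a camera parameter file, validating every view.

    Azimuths of exactly 360 degrees are normalized to 0 with a warning;
    any missing field or invalid rotation raises
    :class:`CameraSchemaError` naming the offending field.
    """
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise CameraSchemaError(f"not valid JSON: {exc}") from exc
    if payload.get("schema") != CAMERA_SCHEMA:
        raise CameraSchemaError(f"unknown or missing schema (expected {CAMERA_SCHEMA})")
    views = []
    for i, obj in enumerate(payload.get("views", [])):
        for f in _REQUIRED_FIELDS:
            if f not in obj:
                raise CameraSchemaError(f"view {i}: missing field '{f}'")
        if len(obj["radial_distortion"]) != 2:
            raise CameraSchemaError(
                f"view {i}: radial_distortion must have exactly 2 coefficients"
            )
        if len(obj["tangential_distortion"]) != 2:
            raise CameraSchemaError(
                f"view {i}: tangential_distortion must have exactly 2 coefficients"
            )
        az = float(obj["azimuth_deg"])
        if az == 360.0:
            warnings.warn(
                f"view {i}: azimuth 360 normalized to 0", stacklevel=2
            )
            az = 0.0
        try:
            views.append(
                CameraView(
                    view_id=str(obj["view_id"]),
                    azimuth_deg=az,
                    focal=tuple(obj["focal"]),
                    principal_point=tuple(obj["principal_point"]),
                    skew=float(obj["skew"]),
                    radial_distortion=tuple(obj["radial_distortion"]),
                    tangential_distortion=tuple(obj["tangential_distortion"]),
                    rotation=np.asarray(obj["rotation"], dtype=float),
                    translation=np.asarray(obj["translation"], dtype=float),
                    image_size=tuple(obj["image_size"]),
                )
            )
        except CameraSchemaError as exc:
            raise CameraSchemaError(f"view {i}: {exc}") from exc
    azimuths = [v.azimuth_deg for v in views]
    if len(set(azimuths)) != len(azimuths):
        raise CameraSchemaError("azimuths are not pairwise distinct (field: azimuth_deg)")
    return views


def reprojection_error(
    points3d: np.ndarray, observed_pixels: np.ndarray, cam: CameraView
) -> float:
    """RMS Euclidean pixel distance between projections and observations."""
    pts = np.asarray(points3d, dtype=float).reshape(-1, 3)
    obs = np.asarray(observed_pixels, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("empty correspondence set")
    if len(pts) != len(obs):
        raise ValueError("points3d and observed_pixels must have equal length")
    uv, in_front = project(pts, cam)
    if not np.all(in_front):
        raise ValueError("correspondence point behind the camera")
    d2 = np.sum((uv - obs) ** 2, axis=1)
    return float(np.sqrt(np.mean(d2)))
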