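"""Side-view plant segmentation.

Turns one RGB side-view image plus its plant-free background frame into
a clean single-component binary silhouette via the chain

    register -> frame difference -> green superimposition
             -> HSV threshold -> morphological cleanup.

The imaging chamber background is homogeneous, so simple frame
differencing extracts the foreground; green superimposition then drops
non-plant differences (soil, films, lighting changes), an HSV band keeps
plant-coloured pixels, and morphology plus largest-component selection
yields one connected silhouette per view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.color import rgb2gray, rgb2hsv
from skimage.feature import ORB, match_descriptors
from skimage.measure import ransac
from skimage.morphology import dilation, disk, erosion
from skimage.transform import SimilarityTransform, warp

__all__ = [
    "HsvRanges",
    "Silhouette",
    "SegmentationConfig",
    "register_to_background",
    "frame_difference",
    "green_superimpose",
    "hsv_threshold",
    "morph_clean",
    "segment_view",
]


@dataclass(frozen=True)
class HsvRanges:
    """Inclusive HSV band, each channel on [0, 1].

    Defaults are an empirically effective band for green plant tissue
    under greenhouse chamber lighting; they are setup-dependent and fully
    overridable.  Hue is on a [0, 1) circular scale; the default green
    band does not straddle 0, so no wraparound handling is applied.
    """

    hue: tuple[float, float] = (0.051, 0.503)
    saturation: tuple[float, float] = (0.102, 0.804)
    value: tuple[float, float] = (0.000, 0.786)

    def __post_init__(self) -> None:
        for name in ("hue", "saturation", "value"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} range must satisfy 0 <= lo <= hi <= 1")

    def contains(self, hsv: np.ndarray) -> np.ndarray:
        """Boolean mask of HSV pixels inside the band (inclusive bounds)."""
        h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
        return (
            (h >= self.hue[0]) & (h <= self.hue[1])
            & (s >= self.saturation[0]) & (s <= self.saturation[1])
            & (v >= self.value[0]) & (v <= self.value[1])
        )


@dataclass
class Silhouette:
    """Registered binary plant mask for one view (True = plant)."""

    mask: np.ndarray
    view_id: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class SegmentationConfig:
    """Parameters of the segmentation chain with package defaults."""

    hsv: HsvRanges = field(default_factory=HsvRanges)
    diff_threshold: float = 15.0 / 255.0
    erosion_radius: int = 1
    dilation_radius: int = 1
    min_area: int = 200
    register: bool = True
    min_inliers: int = 10

    def to_dict(self) -> dict:
        return {
            "hsv": {
                "hue": list(self.hsv.hue),
                "saturation": list(self.hsv.saturation),
                "value": list(self.hsv.value),
            },
            "diff_threshold": self.diff_threshold,
            "erosion_radius": self.erosion_radius,
            "dilation_radius": self.dilation_radius,
            "min_area": self.min_area,
            "register": self.register,
            "min_inliers": self.min_inliers,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentationConfig":
        d = dict(d)
        hsv = d.pop("hsv", None)
        cfg = cls(**d)
        if hsv is not None:
            cfg.hsv = HsvRanges(
                hue=tuple(hsv["hue"]),
                saturation=tuple(hsv["saturation"]),
                value=tuple(hsv["value"]),
            )
        return cfg


def _as_float(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.dtype == np.uint8:
        return img.astype(float) / 255.0
    return img.astype(float)


def register_to_background(
    image: np.ndarray,
    background: np.ndarray,
    min_inliers: int = 10,
    n_keypoints: int = 400,
) -> tuple[np.ndarray, SimilarityTransform]:
    """Align ``image`` to ``background`` by a similarity transform.

    Keypoints (ORB) are matched between the two frames and a
    scale+rotation+translation model is estimated by RANSAC; this
    absorbs zoom-level changes between the background capture and the
    plant capture.  If fewer than ``min_inliers`` matches survive (e.g.
    featureless or pure-noise frames) the identity transform is returned
    with a warning.
    """
    img = _as_float(image)
    bg = _as_float(background)
    if img.ndim != bg.ndim or (img.ndim == 3 and img.shape[2] != bg.shape[2]):
        raise ValueError("image and background must have the same channel count")
    gray_img = rgb2gray(img) if img.ndim == 3 else img
    gray_bg = rgb2gray(bg) if bg.ndim == 3 else bg

    tform = SimilarityTransform()
    try:
        orb_i = ORB(n_keypoints=n_keypoints)
        orb_i.detect_and_extract(gray_img)
        orb_b = ORB(n_keypoints=n_keypoints)
        orb_b.detect_and_extract(gray_bg)
        matches = match_descriptors(
            orb_i.descriptors, orb_b.descriptors, cross_check=True
        )
        src = orb_i.keypoints[matches[:, 0]][:, ::-1]  # (row,col) -> (x,y)
        dst = orb_b.keypoints[matches[:, 1]][:, ::-1]
        if len(src) < max(min_inliers, 3):
            raise RuntimeError("too few matches")
        model, inliers = ransac(
            (src, dst),
            SimilarityTransform,
            min_samples=3,
            residual_threshold=2.0,
            max_trials=500,
            rng=0,
        )
        if model is None or inliers is None or inliers.sum() < min_inliers:
            raise RuntimeError("too few RANSAC inliers")
        tform = model
    except Exception:
        warnings.warn(
            "registration fell back to the identity transform "
            "(insufficient keypoint matches)",
            stacklevel=2,
        )
        registered = img
        return registered, SimilarityTransform()

    registered = warp(img, tform.inverse, preserve_range=True, order=1)
    if registered.shape != img.shape:
        raise ValueError("registered image size mismatch")
    return registered, tform


def frame_difference(
    image: np.ndarray, background: np.ndarray, diff_threshold: float = 15.0 / 255.0
) -> np.ndarray:
    """Foreground mask: max-channel absolute difference above threshold."""
    img = _as_float(image)
    bg = _as_float(background)
    if img.shape != bg.shape:
        raise ValueError("image and background sizes differ")
    diff = np.abs(img - bg)
    if diff.ndim == 3:
        diff = diff.max(axis=2)
    return diff > diff_threshold


def green_superimpose(
    original: np.ndarray, mask: np.ndarray, ranges: HsvRanges | None = None
) -> np.ndarray:
    """Superimpose the plant-coloured pixels of ``original`` onto ``mask``.

    Output pixel = original pixel where the difference mask is set AND
    the pixel passes the green (HSV band) test; zero elsewhere.  Noisy
    differing pixels of other colours (soil, film, lighting) are thus
    returned to the background.
    """
    img = _as_float(original)
    if img.ndim != 3:
        raise ValueError("original must be an RGB image")
    ranges = ranges or HsvRanges()
    green = ranges.contains(rgb2hsv(img))
    keep = np.asarray(mask, dtype=bool) & green
    return img * keep[..., None]


def hsv_threshold(color_foreground: np.ndarray, ranges: HsvRanges | None = None) -> np.ndarray:
    """Binary mask of pixels whose HSV lies inside the band (inclusive)."""
    img = _as_float(color_foreground)
    if img.ndim != 3:
        raise ValueError("expected an RGB image")
    ranges = ranges or HsvRanges()
    return ranges.contains(rgb2hsv(img))


def morph_clean(
    binary: np.ndarray,
    erosion_radius: int = 1,
    dilation_radius: int = 1,
    min_area: int = 200,
) -> np.ndarray:
    """Erode, dilate, and keep the largest 8-connected component.

    Erosion removes speckle noise, dilation refills and closes small
    interior holes, and the largest connected component is kept only if
    its area reaches ``min_area`` (else the mask is empty).
    """
    mask = np.asarray(binary, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    if erosion_radius > 0:
        mask = erosion(mask, disk(erosion_radius))
    if dilation_radius > 0:
        mask = dilation(mask, disk(dilation_radius))
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.zeros_like(mask)
    counts = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(counts)) + 1
    if counts[best - 1] < min_area:
        return np.zeros_like(mask)
    return labels == best


def segment_view(
    image: np.ndarray,
    background: np.ndarray,
    config: SegmentationConfig | None = None,
    view_id: str = "",
) -> Silhouette:
    """Full segmentation chain for one view; deterministic given config."""
    cfg = config or SegmentationConfig()
    img = _as_float(image)
    bg = _as_float(background)
    if cfg.register:
        img, _ = register_to_background(img, bg, min_inliers=cfg.min_inliers)
    diff = frame_difference(img, bg, cfg.diff_threshold)
    fg = green_superimpose(img, diff, cfg.hsv)
    raw = hsv_threshold(fg, cfg.hsv)
    clean = morph_clean(raw, cfg.erosion_radius, cfg.dilation_radius, cfg.min_area)
    return Silhouette(mask=clean, view_id=view_id)
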