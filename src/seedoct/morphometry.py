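"""Camera-image morphometry: seed segmentation, boundary, diameter, wrinkles.

Boundary recognition follows the classic four-step recipe: (1) per-channel
binarization with inclusive thresholds 62–255 / 45–255 / 30–255 on R/G/B,
(2) mask formation as the AND of the channel tests with the water-surface
shadow band excluded, (3) Canny edge detection on the mask, (4) overlay of
the recognized boundary on the original image.

Seed size is reported as the equivalent-circle diameter (Feret available as
an option); the surface-wrinkle indicator is the first persistent frame whose
boundary roughness (sd of radial residuals from the best-fit circle, relative
to the radius) exceeds the baseline level.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import feature, measure

__all__ = [
    "CameraImage",
    "SeedOutline",
    "segment_seed",
    "canny_boundary",
    "overlay_boundary",
    "measure_diameter",
    "wrinkle_index",
    "outline_from_image",
]

DEFAULT_THRESHOLDS = ((62, 255), (45, 255), (30, 255))


@dataclass
class CameraImage:
    """8-bit RGB photo with physical pixel scale and acquisition time."""

    pixels: np.ndarray
    pixel_scale_mm: float = 11.0 / 644.0
    timestamp_h: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("camera image must be H x W x 3")
        if self.pixels.dtype != np.uint8:
            raise ValueError("camera image must be 8-bit")

    @classmethod
    def load(cls, path: str | Path, pixel_scale_mm: float = 11.0 / 644.0,
             timestamp_h: float = 0.0) -> "CameraImage":
        return cls(iio.imread(path)[..., :3], pixel_scale_mm, timestamp_h)


@dataclass
class SeedOutline:
    """Segmented seed: mask, subpixel closed boundary, size and roughness."""

    mask: np.ndarray
    boundary: np.ndarray          # (N, 2) subpixel (row, col) chain
    pixel_scale_mm: float
    timestamp_h: float = 0.0

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def equivalent_diameter_mm(self) -> float:
        return 2.0 * np.sqrt(self.area_px / np.pi) * self.pixel_scale_mm

    def circle_fit(self) -> tuple[np.ndarray, float, float]:
        """Centre, mean radius (px), and sd of radial residuals (px)."""
        pts = self.boundary
        center = pts.mean(axis=0)
        r = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])
        return center, float(r.mean()), float(r.std())

    @property
    def roughness(self) -> float:
        """sd of radial residuals from the best-fit circle, relative to radius."""
        _, r_mean, r_sd = self.circle_fit()
        if r_mean <= 0:
            return float("nan")
        return r_sd / r_mean


def segment_seed(
    image: CameraImage,
    thresholds: Sequence[tuple[int, int]] = DEFAULT_THRESHOLDS,
    water_line_frac: float = 0.7,
) -> np.ndarray:
    """Binary seed mask: AND of inclusive per-channel in-range tests.

    Connected components are labelled and the largest component whose centroid
    lies above the water line is kept, excluding the water-surface shadow
    band.  Raises ``ValueError("no seed found")`` when nothing qualifies.
    """
    px = image.pixels
    mask = np.ones(px.shape[:2], dtype=bool)
    for ch, (lo, hi) in enumerate(thresholds):
        mask &= (px[..., ch] >= lo) & (px[..., ch] <= hi)
    labels = measure.label(mask)
    water_row = water_line_frac * px.shape[0]
    best_area, best_label = 0, 0
    for region in measure.regionprops(labels):
        if region.centroid[0] < water_row and region.area > best_area:
            best_area, best_label = region.area, region.label
    if best_label == 0:
        raise ValueError("no seed found")
    return labels == best_label


def canny_boundary(
    image: np.ndarray,
    sigma: float = 1.4,
    low_frac: float = 0.1,
    high_frac: float = 0.2,
) -> np.ndarray:
    """One-pixel-wide Canny edges; hysteresis thresholds as fractions of the
    maximum gradient magnitude (Gaussian smoothing → orthogonal gradient pair
    → magnitude/direction → non-maximum suppression → double-threshold
    hysteresis)."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.max() > img.min():
        img = (img - img.min()) / (img.max() - img.min())
    smoothed = gaussian_filter(img, sigma)
    gy, gx = np.gradient(smoothed)
    gmax = float(np.hypot(gx, gy).max())
    if gmax == 0:
        return np.zeros(img.shape, dtype=bool)
    return feature.canny(img, sigma=sigma,
                         low_threshold=low_frac * gmax, high_threshold=high_frac * gmax)


def overlay_boundary(
    image: CameraImage,
    edges: np.ndarray,
    color: tuple[int, int, int] = (0, 0, 255),
) -> CameraImage:
    """Recolor boundary pixels on a copy of the image (original untouched)."""
    if edges.shape != image.pixels.shape[:2]:
        raise ValueError("edge map shape does not match image")
    out = image.pixels.copy()
    out[edges] = color
    return CameraImage(out, image.pixel_scale_mm, image.timestamp_h)


def outline_from_image(
    image: CameraImage,
    thresholds: Sequence[tuple[int, int]] = DEFAULT_THRESHOLDS,
    water_line_frac: float = 0.7,
) -> SeedOutline:
    """Segment and trace the seed boundary at subpixel precision."""
    mask = segment_seed(image, thresholds, water_line_frac)
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("no seed boundary found")
    boundary = max(contours, key=len)
    return SeedOutline(mask, boundary, image.pixel_scale_mm, image.timestamp_h)


def measure_diameter(
    outline: SeedOutline,
    pixel_scale_mm: float | None = None,
    method: str = "equivalent",
) -> float:
    """Seed diameter in mm: equivalent-circle (default) or maximum Feret."""
    scale = outline.pixel_scale_mm if pixel_scale_mm is None else pixel_scale_mm
    if outline.area_px == 0:
        raise ValueError("empty outline")
    if method == "equivalent":
        return 2.0 * np.sqrt(outline.area_px / np.pi) * scale
    if method == "feret":
        props = measure.regionprops(outline.mask.astype(int))[0]
        return float(props.feret_diameter_max) * scale
    raise ValueError(f"unknown method {method!r}")


def wrinkle_index(
    outlines: Sequence[SeedOutline | None],
    times_h: Sequence[float],
    *,
    baseline_frames: int = 5,
    persistence: int = 2,
    min_roughness: float = 4e-3,
):
    """Boundary-roughness series and surface-wrinkle onset.

    Onset is the first persistent frame whose roughness strictly exceeds
    ``max(baseline mean + 3 × baseline sd, min_roughness)`` where the baseline
    is taken over the first ``baseline_frames`` frames.  ``None`` outlines
    (degenerate frames) are skipped with a NaN roughness.  Returns
    ``(roughness array, Detection | None)``.
    """
    from .indicators import Detection, _first_persistent

    if len(outlines) < 2:
        raise ValueError("need at least two frames")
    rough = np.array([np.nan if o is None else o.roughness for o in outlines])
    base = rough[:baseline_frames]
    base = base[np.isfinite(base)]
    if base.size == 0:
        raise ValueError("no valid baseline frames")
    threshold = max(float(base.mean() + 3.0 * base.std()), min_roughness)
    flags = np.where(np.isfinite(rough), rough > threshold, False)
    i = _first_persistent(flags, persistence)
    det = None
    if i is not None:
        det = Detection(float(times_h[i]), i,
                        [f"roughness {rough[i]:.4f} > threshold {threshold:.4f}"])
    return rough, det
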