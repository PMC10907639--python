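"""Span, chord, and area measurement from plan-view silhouette images.

Definitions: span S is the longest dimension of the whole silhouette
(maximum distance between foreground pixel centres), chord c the maximum
extent perpendicular to the span line, and area A the foreground pixel
count scaled to physical units.  The span is computed on the convex hull
of the foreground, which provably attains the all-pairs maximum; ties are
broken toward the lexicographically smallest (row, col) endpoint pair so
repeated runs are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.filters import threshold_otsu
from skimage.measure import label

from .errors import DomainError, SegmentationError

__all__ = [
    "Silhouette",
    "segment_silhouette",
    "measure_span",
    "measure_chord",
    "measure_area",
    "measure_all",
    "MIN_FOREGROUND_PIXELS",
]

MIN_FOREGROUND_PIXELS = 50


@dataclass(frozen=True)
class Silhouette:
    """Binary mask (True = samara) with its mm-per-pixel scale.

    Pixel (0, 0) is the top-left corner; indices are 0-based (row, col).
    """

    mask: np.ndarray
    scale_mm_per_px: float

    def __post_init__(self):
        if self.scale_mm_per_px <= 0:
            raise DomainError("scale must be positive (mm per pixel)")
        if self.mask.ndim != 2 or self.mask.dtype != bool:
            raise DomainError("mask must be a 2-D boolean array")

    @property
    def points(self) -> np.ndarray:
        """Foreground pixel centres as float (row, col) coordinates."""
        return np.argwhere(self.mask).astype(float)


def segment_silhouette(image: np.ndarray, threshold: float | None = None,
                       polarity: str = "dark",
                       min_pixels: int = MIN_FOREGROUND_PIXELS,
                       scale_mm_per_px: float = 1.0) -> Silhouette:
    """Extract the largest connected silhouette from a greyscale image.

    Otsu's threshold is used unless an explicit ``threshold`` is given.
    ``polarity`` selects dark-on-light (``dark``, the tabletop-photograph
    default) or light-on-dark (``light``) foreground.  The largest
    8-connected component is kept and its holes filled.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0 or img.ndim != 2:
        raise SegmentationError("image must be a non-empty 2-D array")
    if threshold is None:
        if np.ptp(img) == 0:
            raise SegmentationError(
                "uniform image: no threshold separates foreground "
                f"(minimum component size {min_pixels} px not reached)")
        threshold = float(threshold_otsu(img))
    if polarity == "dark":
        fg = img < threshold
    elif polarity == "light":
        fg = img > threshold
    else:
        raise DomainError(f"unknown polarity {polarity!r}")
    labels = label(fg, connectivity=2)
    if labels.max() == 0:
        raise SegmentationError(
            f"no foreground component >= {min_pixels} px at threshold {threshold:g}")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    biggest = int(np.argmax(counts))
    if counts[biggest] < min_pixels:
        raise SegmentationError(
            f"largest component has {counts[biggest]} px (< {min_pixels}) "
            f"at threshold {threshold:g}")
    mask = ndimage.binary_fill_holes(labels == biggest)
    return Silhouette(mask=mask, scale_mm_per_px=scale_mm_per_px)


def _hull_points(points: np.ndarray) -> np.ndarray:
    if len(points) < 3:
        return points
    try:
        hull = ConvexHull(points)
    except QhullError:  # collinear pixel set
        return points
    return points[hull.vertices]


def _span_pair(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Farthest pixel pair, lexicographic tie-break, via the convex hull."""
    pts = _hull_points(points)
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    dmax = float(d2.max())
    ii, jj = np.nonzero(d2 >= dmax - 1e-9)
    pairs = sorted(
        tuple(sorted((tuple(pts[i]), tuple(pts[j]))))
        for i, j in zip(ii, jj) if i < j
    )
    p1, p2 = (np.array(p) for p in pairs[0])
    return p1, p2, float(np.sqrt(dmax))


def measure_span(s: Silhouette) -> float:
    """Span in mm: maximum distance between foreground pixel centres."""
    pts = s.points
    if len(pts) < 2:
        raise DomainError("silhouette has fewer than 2 foreground pixels")
    _, _, dist = _span_pair(pts)
    return dist * s.scale_mm_per_px


def measure_chord(s: Silhouette) -> float:
    """Chord in mm: foreground extent perpendicular to the span line.

    Degenerate (collinear) silhouettes report one pixel-width with a
    warning rather than zero.
    """
    pts = s.points
    if len(pts) < 2:
        raise DomainError("silhouette has fewer than 2 foreground pixels")
    p1, p2, dist = _span_pair(pts)
    u = (p2 - p1) / dist
    perp = np.array([-u[1], u[0]])
    proj = _hull_points(pts) @ perp
    extent = float(proj.max() - proj.min())
    if extent < 1.0:
        warnings.warn("degenerate (collinear) silhouette; chord floored at "
                      "one pixel", stacklevel=2)
        extent = 1.0
    return extent * s.scale_mm_per_px


def measure_area(s: Silhouette) -> float:
    """Plan-view area in cm²: pixel count x scale², 100 mm² = 1 cm²."""
    count = int(s.mask.sum())
    return count * s.scale_mm_per_px**2 / 100.0


def measure_all(s: Silhouette) -> dict:
    """Span, chord, area, and the span endpoints (pixel coords) for audit."""
    p1, p2, dist = _span_pair(s.points)
    span_mm = dist * s.scale_mm_per_px
    u = (p2 - p1) / dist
    perp = np.array([-u[1], u[0]])
    proj = _hull_points(s.points) @ perp
    chord_mm = max(float(proj.max() - proj.min()), 1.0) * s.scale_mm_per_px
    return {
        "span_mm": span_mm,
        "chord_mm": chord_mm,
        "area_cm2": measure_area(s),
        "span_endpoints_rc": [[float(p1[0]), float(p1[1])],
                              [float(p2[0]), float(p2[1])]],
        "foreground_px": int(s.mask.sum()),
        "scale_mm_per_px": s.scale_mm_per_px,
    }
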