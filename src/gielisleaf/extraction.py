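"""Boundary extraction from scanned (or synthetically rendered) leaf images.

A scan is reduced to a calibrated :class:`~gielisleaf.geometry.BoundaryCurve`
in three deterministic steps: binarize (fixed or Otsu threshold, holes
filled, largest connected component kept), trace the sub-pixel contour by
marching squares at the 0.5 level, and convert to physical units in
mathematical axes (y up, origin at the image's lower-left corner).

Petioles/pseudo-petioles are not segmented away; scans should present the
blade only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage import filters, measure

from .geometry import BoundaryCurve

__all__ = [
    "LeafImage",
    "ExtractionError",
    "binarize",
    "extract_boundary",
    "measure_length",
    "dpi_to_scale",
]

INCH_CM = 2.54


class ExtractionError(RuntimeError):
    """Image could not be reduced to a single leaf boundary."""


def dpi_to_scale(dpi: float) -> float:
    """Convert scanner resolution (dots per inch) to cm per pixel."""
    if dpi <= 0:
        raise ValueError("dpi must be positive")
    return INCH_CM / dpi


@dataclass(frozen=True)
class LeafImage:
    """A 2D intensity grid with its physical calibration.

    ``pixels`` is row-major with y increasing downward (image convention);
    ``scale`` is the physical size of one pixel in cm.
    """

    pixels: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2D grid")
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise ValueError("scale (cm/px) must be positive")
        object.__setattr__(self, "pixels", px)

    @classmethod
    def from_file(cls, path, scale: float | None = None, dpi: float | None = None):
        """Load a PNG/TIFF image; color is collapsed to luminance."""
        if (scale is None) == (dpi is None):
            raise ValueError("give exactly one of scale (cm/px) or dpi")
        arr = np.asarray(iio.imread(path), dtype=float)
        if arr.ndim == 3:  # RGB(A) -> luminance
            arr = arr[..., :3].mean(axis=-1)
        return cls(arr, scale if scale is not None else dpi_to_scale(dpi))


def binarize(image: LeafImage, method="otsu") -> np.ndarray:
    """Reduce an image to a boolean leaf mask.

    ``method`` is either ``"otsu"`` (automatic threshold) or a fixed float
    threshold.  Foreground polarity is chosen automatically as the class
    with the smaller presence on the image border — a leaf never wraps the
    frame, whereas scanner background does.  Holes are filled and only the
    largest connected component survives.  Already-binary masks pass
    through unchanged (up to hole filling/component selection), with the
    nonzero class as foreground.
    """
    px = image.pixels
    values = np.unique(px)
    if values.size == 1:
        raise ExtractionError("uniform image: nothing to segment")
    if values.size == 2 and set(values) <= {0.0, 1.0}:
        fg = px > 0.5
    else:
        thr = filters.threshold_otsu(px) if method == "otsu" else float(method)
        fg = px > thr
        border = np.concatenate([fg[0], fg[-1], fg[:, 0], fg[:, -1]])
        if border.mean() > 0.5:  # bright class wraps the frame -> it is paper
            fg = ~fg
    if not fg.any() or fg.all():
        raise ExtractionError("binarization produced an empty or full mask")
    fg = ndimage.binary_fill_holes(fg)
    labels, nlab = ndimage.label(fg)
    if nlab > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, nlab + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    return fg


def extract_boundary(
    mask: np.ndarray, scale: float, num_points: int = 2000
) -> BoundaryCurve:
    """Trace the sub-pixel outline of a binary leaf mask.

    Marching squares at intensity level 0.5 yields a contour through the
    midpoints between foreground and background pixel centers, which
    removes most of the quantization bias of pixel-edge tracing.  The
    contour is re-sampled uniformly by arc length to ``num_points``
    vertices, oriented counter-clockwise, flipped to mathematical axes
    (y up, origin lower-left) and scaled to cm.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ExtractionError("empty mask")
    _, nlab = ndimage.label(mask)
    if nlab != 1:
        raise ExtractionError(f"expected exactly one component, found {nlab}")
    if mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any():
        warnings.warn(
            "foreground touches the image border; the leaf may be cropped",
            stacklevel=2,
        )
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ExtractionError("no contour found at level 0.5")
    contour = max(contours, key=len)  # (row, col), closed (first == last)
    rows, cols = contour[:, 0], contour[:, 1]
    x = cols * scale
    y = (mask.shape[0] - 1 - rows) * scale
    pts = _resample_closed(np.column_stack([x, y]), num_points)
    # enforce counter-clockwise orientation (positive signed area)
    signed = 0.5 * np.sum(
        pts[:, 0] * np.roll(pts[:, 1], -1) - np.roll(pts[:, 0], -1) * pts[:, 1]
    )
    if signed < 0:
        pts = pts[::-1]
    return BoundaryCurve(pts, units="cm", closed=True)


def _resample_closed(pts: np.ndarray, num_points: int) -> np.ndarray:
    """Uniform arc-length resampling of a closed polyline (first==last)."""
    if not np.all(pts[0] == pts[-1]):
        pts = np.vstack([pts, pts[0]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        raise ExtractionError("degenerate zero-length contour")
    target = total * np.arange(num_points) / num_points
    return np.column_stack(
        [np.interp(target, s, pts[:, 0]), np.interp(target, s, pts[:, 1])]
    )


def measure_length(curve_or_points) -> float:
    """Blade length as the maximal pairwise point distance (diameter).

    Computed exactly on the convex hull; rigid-motion invariant.  Accepts
    a BoundaryCurve or a bare (N, 2) point array (N >= 2).
    """
    pts = (
        curve_or_points.points
        if isinstance(curve_or_points, BoundaryCurve)
        else np.asarray(curve_or_points, dtype=float)
    )
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need at least two planar points")
    hull_pts = pts
    if len(pts) > 16:
        try:
            from scipy.spatial import ConvexHull

            hull_pts = pts[ConvexHull(pts).vertices]
        except Exception:  # collinear/degenerate input: brute force below
            hull_pts = pts
    # chunked pairwise max keeps memory bounded on near-convex outlines,
    # where almost every point survives to the hull
    best = 0.0
    for start in range(0, len(hull_pts), 512):
        chunk = hull_pts[start : start + 512]
        d2 = np.sum((chunk[:, None, :] - hull_pts[None, :, :]) ** 2, axis=-1)
        best = max(best, float(d2.max()))
    return float(np.sqrt(best))
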