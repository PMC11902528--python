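"""Binary-mask primitives and segmentation-quality metrics.

A *mask* throughout this package is a 2-D boolean :class:`numpy.ndarray`
(row-major, 0-based, y increasing downward).  This module provides the
bilinear resize operator used by the incoherent-region construction, the
plain / boundary / amodal IoU metrics, and a Laplacian boundary-mask
baseline.

Conventions
-----------
* Bounding boxes are half-open: ``[x0, x1) x [y0, y1)``.
* Interpolated mask values are binarized at 0.5 with ties counted as
  foreground.
* The boundary-IoU band of a mask ``X`` is the *inner* band ``X ∩ Xd``
  where ``Xd`` is the set of pixels whose Euclidean distance to the
  background (anything outside ``X``, including beyond the image border)
  is at most ``d``.
* A metric of two empty masks is 1.0 (perfect agreement); empty versus
  nonempty is 0.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "BBox",
    "MetricResult",
    "as_mask",
    "resize_bilinear",
    "resize_mask",
    "plain_iou",
    "boundary_iou",
    "amodal_iou",
    "laplacian_boundary",
    "mask_bbox",
]

# Binarization threshold for interpolated masks.  The tiny slack keeps the
# "ties count as foreground" rule stable under reordered float summation.
_BIN_THRESHOLD = 0.5 - 1e-9


@dataclass(frozen=True)
class BBox:
    """Half-open pixel box ``[x0, x1) x [y0, y1)``."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError(f"degenerate box {self!r}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def diagonal(self) -> float:
        return float(np.hypot(self.width, self.height))

    def intersects(self, other: "BBox") -> bool:
        return (
            self.x0 < other.x1
            and other.x0 < self.x1
            and self.y0 < other.y1
            and other.y0 < self.y1
        )

    def crop(self, arr: np.ndarray) -> np.ndarray:
        """Crop a 2-D (or 2-D + channels) array to this box, clipped to bounds."""
        y0 = max(self.y0, 0)
        x0 = max(self.x0, 0)
        return arr[y0 : self.y1, x0 : self.x1]


@dataclass(frozen=True)
class MetricResult:
    """A scalar mask-agreement score in [0, 1]."""

    value: float
    kind: str
    d: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"metric value {self.value} outside [0, 1]")


def as_mask(arr: np.ndarray) -> np.ndarray:
    """Validate and coerce an array to a 2-D boolean mask."""
    m = np.asarray(arr)
    if m.ndim != 2 or m.shape[0] < 1 or m.shape[1] < 1:
        raise ValueError(f"mask must be 2-D and nonempty, got shape {m.shape}")
    return m.astype(bool)


def _require_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def mask_bbox(m: np.ndarray) -> BBox | None:
    """Tight bounding box of a mask's support, or None for an empty mask."""
    m = as_mask(m)
    ys, xs = np.nonzero(m)
    if ys.size == 0:
        return None
    return BBox(int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)


def _interp_weights(n_in: int, n_out: int) -> np.ndarray:
    """Sparse-as-dense (n_out, n_in) bilinear weight matrix.

    Output pixel centers are mapped into the input grid with the
    half-pixel-center convention ``x_in = (x_out + 0.5) * n_in/n_out - 0.5``
    and samples are clamped to the edge.
    """
    scale = n_in / n_out
    x = (np.arange(n_out) + 0.5) * scale - 0.5
    lo = np.floor(x).astype(int)
    t = x - lo
    lo0 = np.clip(lo, 0, n_in - 1)
    lo1 = np.clip(lo + 1, 0, n_in - 1)
    w = np.zeros((n_out, n_in))
    rows = np.arange(n_out)
    np.add.at(w, (rows, lo0), 1.0 - t)
    np.add.at(w, (rows, lo1), t)
    return w


def resize_bilinear(img: np.ndarray, target_h: int, target_w: int) -> np.ndarray:
    """Separable bilinear resize of a 2-D float array (no anti-aliasing)."""
    if target_h < 1 or target_w < 1:
        raise ValueError("target size must be positive")
    a = np.asarray(img, dtype=np.float64)
    if a.ndim != 2:
        raise ValueError("expected a 2-D array")
    if a.shape == (target_h, target_w):
        return a.copy()
    wr = _interp_weights(a.shape[0], target_h)
    wc = _interp_weights(a.shape[1], target_w)
    return wr @ a @ wc.T


def resize_mask(m: np.ndarray, target_h: int, target_w: int) -> np.ndarray:
    """Bilinearly resize a binary mask and re-binarize at 0.5 (ties -> 1)."""
    m = as_mask(m)
    if target_h < 1 or target_w < 1:
        raise ValueError("target size must be positive")
    if m.shape == (target_h, target_w):
        return m.copy()
    return resize_bilinear(m.astype(np.float64), target_h, target_w) >= _BIN_THRESHOLD


def plain_iou(a: np.ndarray, b: np.ndarray) -> MetricResult:
    """Intersection-over-union of two equal-shape masks."""
    a, b = as_mask(a), as_mask(b)
    _require_same_shape(a, b)
    union = np.count_nonzero(a | b)
    if union == 0:
        return MetricResult(1.0, "iou")
    inter = np.count_nonzero(a & b)
    return MetricResult(inter / union, "iou")


def amodal_iou(ga: np.ndarray, pa: np.ndarray) -> MetricResult:
    """IoU between a ground-truth complete (amodal) mask and a prediction.

    Numerically identical to :func:`plain_iou`; kept as a named metric
    because it is the headline score of the de-occlusion task: it compares
    the *completed* mask of an occluded instance against the true full
    extent, hidden parts included.
    """
    r = plain_iou(ga, pa)
    return MetricResult(r.value, "amodal_iou")


def _inner_band(x: np.ndarray, d: float) -> np.ndarray:
    """Pixels of ``x`` within Euclidean distance ``d`` of the background.

    The image border counts as background, so a mask flush against the
    border still has a band there.
    """
    padded = np.pad(x, 1, mode="constant", constant_values=False)
    dist = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
    return x & (dist <= d)


def boundary_iou(
    g: np.ndarray, p: np.ndarray, d: float | str = "auto"
) -> MetricResult:
    """IoU restricted to d-pixel inner boundary bands of both masks.

    ``d="auto"`` follows the 2%-of-instance-diagonal convention, measured on
    the ground-truth mask's tight bounding box with a floor of 1 px.
    """
    g, p = as_mask(g), as_mask(p)
    _require_same_shape(g, p)
    if not np.any(g) and not np.any(p):
        return MetricResult(1.0, "boundary_iou", None)
    if isinstance(d, str):
        if d != "auto":
            raise ValueError(f"d must be a number or 'auto', got {d!r}")
        box = mask_bbox(g)
        diag = box.diagonal if box is not None else 0.0
        d_val = max(1.0, float(round(0.02 * diag)))
    else:
        d_val = float(d)
        if d_val < 1:
            raise ValueError("d must be >= 1")
    gb = _inner_band(g, d_val)
    pb = _inner_band(p, d_val)
    union = np.count_nonzero(gb | pb)
    if union == 0:
        return MetricResult(1.0, "boundary_iou", d_val)
    inter = np.count_nonzero(gb & pb)
    return MetricResult(inter / union, "boundary_iou", d_val)


_LAPLACIAN_8 = np.array([[-1, -1, -1], [-1, 8, -1], [-1, -1, -1]], dtype=np.int64)


def laplacian_boundary(m: np.ndarray) -> np.ndarray:
    """One-pixel boundary mask: nonzero 3x3 Laplacian response within ``m``.

    Used as the baseline supervision signal for the boundary-head variant of
    the dual-decoder model; interior pixels (all eight neighbours set) give a
    zero response and drop out.
    """
    m = as_mask(m)
    resp = ndimage.convolve(
        m.astype(np.int64), _LAPLACIAN_8, mode="constant", cval=0
    )
    return (resp != 0) & m
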