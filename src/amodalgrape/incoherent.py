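"""Incoherent-region supervision masks.

When an annotation mask is resized down for training and back up for use,
pixels near boundaries and instance overlaps change value: these are the
*incoherent regions*.  Supervising a dedicated decoder on them (instead of
on thin Laplacian boundaries) concentrates learning capacity on exactly the
pixels the size transformation corrupts, which in cluster-fruit imagery are
dominated by instance-overlap seams.

Three constructions live here:

``incoherent_mask``
    M_inc = D(m XOR U(D(m))) for bilinear down/up operators D, U — the
    pixels whose value is lost by one size transformation, reported at the
    downsampled size.

``local_incoherent_mask``
    The subset of M_inc lying where two *distinct* instances meet, decided
    by sampling three symmetric pixel pairs per point in a label map.

``build_supervision_triple``
    The per-proposal supervision targets for the dual-decoder heads: the
    cropped-and-resized instance mask, its instance-level incoherent mask,
    and the local (overlap-only) incoherent mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from amodalgrape.mask_core import BBox, as_mask, resize_bilinear, resize_mask

__all__ = [
    "IncoherentMasks",
    "SupervisionTriple",
    "incoherent_mask",
    "scene_incoherent_mask",
    "local_incoherent_mask",
    "build_supervision_triple",
    "resize_labels_nearest",
]

# Symmetric pair directions: horizontal, vertical, main diagonal.
_PAIR_DIRECTIONS = ((0, 1), (1, 0), (1, 1))


@dataclass(frozen=True)
class IncoherentMasks:
    """Full-image incoherent mask and its overlap-only (local) subset."""

    m_inc: np.ndarray
    m_inc_o: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.m_inc_o & ~self.m_inc):
            raise ValueError("local incoherent mask must be a subset of m_inc")


@dataclass
class SupervisionTriple:
    """Per-proposal decoder targets.

    ``mpc``
        instance mask cropped to the proposal, at the mask-decoder output
        size (28 px default);
    ``mpi``
        instance-level incoherent mask of the cropped instance, at the
        incoherent-decoder output size (56 px default);
    ``minc_oi``
        local incoherent mask restricted to the instance, same size as
        ``mpi`` (logical AND construction, hence always a subset);
    ``degenerate``
        True when the proposal missed the instance and all targets are
        zero.
    """

    mpc: np.ndarray
    mpi: np.ndarray
    minc_oi: np.ndarray
    proposal: BBox
    degenerate: bool = False


def incoherent_mask(m: np.ndarray, down_h: int, down_w: int) -> np.ndarray:
    """Pixels lost by a downsample–upsample cycle, at the downsampled size.

    Computes ``D(m XOR U(D(m)))`` with bilinear ``D``/``U``: the mask
    resizes binarize at 0.5 (ties to foreground), while the *final*
    downsample of the difference ribbon marks every output pixel that
    received any lost coverage.  The ribbon of changed pixels is thin, so a
    majority threshold there would erase exactly the signal the mask
    exists to capture; the any-coverage rule keeps the result a faithful
    "value was lost here" map at the downsampled size.

    Requires ``(down_h, down_w)`` no larger than ``m``'s size.
    """
    m = as_mask(m)
    h, w = m.shape
    if down_h > h or down_w > w:
        raise ValueError(
            f"downsample target ({down_h}, {down_w}) exceeds source ({h}, {w})"
        )
    if down_h < 1 or down_w < 1:
        raise ValueError("target size must be positive")
    down = resize_mask(m, down_h, down_w)
    up = resize_mask(down, h, w)
    diff = m ^ up
    return resize_bilinear(diff.astype(np.float64), down_h, down_w) > 1e-9


def resize_labels_nearest(labels: np.ndarray, target_h: int, target_w: int) -> np.ndarray:
    """Nearest-neighbour resize of an integer label map (ids preserved)."""
    lab = np.asarray(labels)
    if lab.shape == (target_h, target_w):
        return lab.copy()
    ys = np.clip(
        np.round((np.arange(target_h) + 0.5) * lab.shape[0] / target_h - 0.5),
        0,
        lab.shape[0] - 1,
    ).astype(int)
    xs = np.clip(
        np.round((np.arange(target_w) + 0.5) * lab.shape[1] / target_w - 0.5),
        0,
        lab.shape[1] - 1,
    ).astype(int)
    return lab[np.ix_(ys, xs)]


def local_incoherent_mask(
    m_inc: np.ndarray, labels: np.ndarray, pair_offset: int = 2
) -> np.ndarray:
    """Restrict an incoherent mask to points where two instances meet.

    For every on-pixel of ``m_inc``, three pixel pairs are sampled symmetric
    about the point at distance ``pair_offset`` along the horizontal,
    vertical, and main-diagonal directions.  A pair straddles two instances
    iff both members are in-bounds and carry two *different nonzero* ids
    (instance-versus-background pairs do not count).  The point is kept iff
    at least two of the three pairs straddle.

    ``labels`` is registered to ``m_inc``'s frame by nearest-neighbour
    resize when the shapes differ.
    """
    if pair_offset < 1:
        raise ValueError("pair_offset must be >= 1")
    m_inc = as_mask(m_inc)
    lab = resize_labels_nearest(np.asarray(labels), *m_inc.shape)

    h, w = m_inc.shape
    r = pair_offset
    n_straddle = np.zeros((h, w), dtype=np.int8)
    ys, xs = np.mgrid[0:h, 0:w]
    for dy, dx in _PAIR_DIRECTIONS:
        y1, x1 = ys + dy * r, xs + dx * r
        y2, x2 = ys - dy * r, xs - dx * r
        valid = (y1 < h) & (x1 < w) & (y2 >= 0) & (x2 >= 0)
        p1 = np.zeros((h, w), dtype=lab.dtype)
        p2 = np.zeros((h, w), dtype=lab.dtype)
        p1[valid] = lab[y1[valid], x1[valid]]
        p2[valid] = lab[y2[valid], x2[valid]]
        straddle = valid & (p1 > 0) & (p2 > 0) & (p1 != p2)
        n_straddle += straddle
    return m_inc & (n_straddle >= 2)


def scene_incoherent_mask(labels: np.ndarray, down_h: int, down_w: int) -> np.ndarray:
    """Union of per-instance incoherent masks of a label map.

    Each instance's silhouette is passed through :func:`incoherent_mask`
    separately and the results are OR-ed: a seam where two instances abut is
    a boundary of *each* instance mask even though it is interior to their
    union, so the per-instance pass is what makes overlap seams show up.
    """
    lab = np.asarray(labels)
    out = np.zeros((down_h, down_w), dtype=bool)
    for k in np.unique(lab):
        if k == 0:
            continue
        out |= incoherent_mask(lab == k, down_h, down_w)
    return out


def _downsample_size(shape: tuple[int, int], image_down) -> tuple[int, int]:
    if image_down is None:
        # Default size transformation: 60% of the source frame, the typical
        # train-time input scaling for proximal cluster images.
        return (max(1, round(shape[0] * 0.6)), max(1, round(shape[1] * 0.6)))
    return (int(image_down[0]), int(image_down[1]))


def build_supervision_triple(
    instance: np.ndarray,
    labels: np.ndarray,
    proposal: BBox,
    mask_out: int = 28,
    inc_out: int = 56,
    image_down: tuple[int, int] | None = None,
    pair_offset: int = 2,
    apply_eq2_to_local: bool = False,
) -> SupervisionTriple:
    """Assemble the per-proposal supervision targets for the dual decoders.

    Pipeline: (1) full-image incoherent mask at the train-time downsample
    size, then its overlap-only subset against ``labels``; (2) the local
    mask is brought back to the image frame and both it and the instance
    mask are cropped by ``proposal``; (3) the instance crop is resized to
    ``mask_out`` (mask-decoder target) and its own incoherent mask at
    ``inc_out`` becomes the incoherent-decoder target; (4) the cropped local
    mask is resized to ``inc_out`` (optionally re-derived through the
    incoherent transform instead, ``apply_eq2_to_local=True``) and ANDed
    with the instance incoherent mask, guaranteeing the subset invariant.

    A proposal that misses the instance yields an all-zero triple flagged
    ``degenerate`` (with a warning).
    """
    instance = as_mask(instance)
    lab = np.asarray(labels)
    if instance.shape != lab.shape:
        raise ValueError("instance mask and label map must share a frame")

    down_h, down_w = _downsample_size(instance.shape, image_down)
    m_inc = scene_incoherent_mask(lab, down_h, down_w)
    m_inc_o = local_incoherent_mask(m_inc, lab, pair_offset=pair_offset)
    # Back to the image frame so the proposal crop applies to both rasters.
    m_inc_o_full = resize_mask(m_inc_o, *instance.shape)

    inst_crop = proposal.crop(instance)
    inc_crop = proposal.crop(m_inc_o_full)
    if inst_crop.size == 0 or not np.any(inst_crop):
        warnings.warn(
            "proposal does not cover the instance; emitting an all-zero "
            "supervision triple",
            stacklevel=2,
        )
        zero_m = np.zeros((mask_out, mask_out), dtype=bool)
        zero_i = np.zeros((inc_out, inc_out), dtype=bool)
        return SupervisionTriple(zero_m, zero_i, zero_i.copy(), proposal, True)

    mpc = resize_mask(inst_crop, mask_out, mask_out)
    if min(inst_crop.shape) >= inc_out:
        mpi = incoherent_mask(inst_crop, inc_out, inc_out)
    else:
        # Crop smaller than the decoder output: emulate a genuine 2x size
        # transformation by working at twice the output resolution.
        working = resize_mask(inst_crop, 2 * inc_out, 2 * inc_out)
        mpi = incoherent_mask(working, inc_out, inc_out)
    if apply_eq2_to_local and min(inc_crop.shape) >= inc_out:
        minc_o_prime = incoherent_mask(inc_crop, inc_out, inc_out)
    elif min(inc_crop.shape) > inc_out:
        # Downsizing a thin supervision ribbon: keep any covered pixel.
        minc_o_prime = (
            resize_bilinear(inc_crop.astype(np.float64), inc_out, inc_out) > 1e-9
        )
    else:
        minc_o_prime = resize_mask(inc_crop, inc_out, inc_out)
    minc_oi = minc_o_prime & mpi
    return SupervisionTriple(mpc, mpi, minc_oi, proposal, False)
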