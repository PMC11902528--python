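"""Occlusion synthesis: overlapping-cover strategy and random-cover baseline.

Training a mask-completion network requires (occluded, occluder, intact)
image triples, which cannot be photographed — once a grape hides another,
the hidden content is gone.  The triples are therefore *synthesized* by
pasting two complete instances from an instance pool so that one covers
part of the other.

The overlapping-cover strategy constrains the paste so the synthetic
occlusions resemble how clusters actually overlap on a vine:

* 8 directional cases (45° sectors): the occluder approaches from one of
  eight directions; corner cases overlap in both axes, cardinal cases in
  one;
* an overlap ratio ``beta`` in (0.2, 0.85] controls the overlap depth;
* a size filter rejects occluders much larger/smaller than the occluded
  instance (0.9 < h_occ/h_occder < 1.2 must hold... see ``size_match``);
* an occlusion-rate filter rejects pastes that hide <= 10% of the occluded
  instance, bumping ``beta`` by 0.05 (capped) and finally resampling;
* *reverse synthesis* (``gamma``): with some probability the sample is an
  identity mapping whose prediction target is the untouched occluder —
  a regularizer that stops the completer from inflating instances that are
  actually in front.

The random-cover baseline pastes the occluder at any offset with bounding
boxes intersecting, with none of the filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from amodalgrape.mask_core import as_mask, mask_bbox, resize_bilinear, resize_mask

__all__ = [
    "PoolItem",
    "InstancePool",
    "SynthesisSample",
    "size_match",
    "occlusion_rate",
    "synthesize_pair",
    "random_cover",
    "build_pool",
    "letterbox_sample",
    "synthesis_stream",
]

BETA_RANGE = (0.2, 0.85)
MIN_OCCLUSION_RATE = 0.1
_MAX_PAIR_ATTEMPTS = 200


@dataclass
class PoolItem:
    """A complete instance tight-cropped to its silhouette's bounding box."""

    rgb: np.ndarray  # (h, w, 3) uint8, zero outside the mask
    mask: np.ndarray  # (h, w) bool, nonempty

    def __post_init__(self) -> None:
        self.mask = as_mask(self.mask)
        if not np.any(self.mask):
            raise ValueError("pool item mask is empty")
        if self.rgb.shape[:2] != self.mask.shape:
            raise ValueError("rgb and mask shapes differ")
        # Foreground pixels must survive the grayscale->bool round trip the
        # synthesis algorithm uses to recover masks from pasted canvases.
        rgb = np.asarray(self.rgb, dtype=np.uint8).copy()
        rgb[~self.mask] = 0
        fg = rgb[self.mask]
        fg[fg.sum(axis=1) == 0] = 1
        rgb[self.mask] = fg
        self.rgb = rgb

    @property
    def height(self) -> int:
        return self.mask.shape[0]

    @property
    def width(self) -> int:
        return self.mask.shape[1]


@dataclass
class InstancePool:
    """An indexable collection of complete instances."""

    items: list[PoolItem] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, i: int) -> PoolItem:
        return self.items[i]


@dataclass
class SynthesisSample:
    """One synthesized (occluded, occluder, intact) training triple.

    All six rasters share the canvas size.  ``case_alpha`` is the
    directional case (1..8; 0 for the random-cover baseline), ``beta`` the
    final overlap ratio after any retries, ``gamma`` whether this is a
    reverse-synthesis (identity) sample, and ``epsilon`` the realized
    occlusion rate of the erased instance.
    """

    i_occ: np.ndarray
    i_occder: np.ndarray
    i_intact: np.ndarray
    m_occ: np.ndarray
    m_occder: np.ndarray
    m_intact: np.ndarray
    case_alpha: int
    beta: float
    gamma: bool
    epsilon: float
    occ_hw: tuple[int, int] | None = None
    occder_hw: tuple[int, int] | None = None


def size_match(h_occ: int, h_occder: int) -> bool:
    """Height compatibility filter between occluded and occluder instances."""
    if h_occ <= 0 or h_occder <= 0:
        raise ValueError("heights must be positive")
    return not (h_occ >= 1.2 * h_occder or h_occ <= 0.9 * h_occder)


def occlusion_rate(visible: np.ndarray, intact: np.ndarray) -> float:
    """Fraction of the intact instance hidden: 1 - |visible| / |intact|."""
    visible, intact = as_mask(visible), as_mask(intact)
    if visible.shape != intact.shape:
        raise ValueError("shape mismatch")
    n_intact = np.count_nonzero(intact)
    if n_intact == 0:
        raise ValueError("intact mask is empty")
    return 1.0 - np.count_nonzero(visible) / n_intact


def _gray(rgb: np.ndarray) -> np.ndarray:
    return np.asarray(rgb, dtype=np.float64).sum(axis=2)


def _canvas_mask(rgb: np.ndarray) -> np.ndarray:
    # Canvases start all-black, so any painted pixel is foreground.
    return _gray(rgb) > 0


def _paste(canvas: np.ndarray, item: PoolItem, y: int, x: int) -> None:
    h, w = item.mask.shape
    region = canvas[y : y + h, x : x + w]
    region[item.mask] = item.rgb[item.mask]


def _case_layout(
    alpha: int,
    occ: PoolItem,
    occder: PoolItem,
    beta: float,
    rng: np.random.Generator,
) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]]:
    """Canvas size and paste origins ((hs, ws), occ_yx, occder_yx).

    Corner cases (alpha even) follow the printed top-right layout (case 2)
    reflected about the canvas axes; cardinal cases (alpha odd) overlap
    along a single axis to depth beta with centred, lightly jittered
    transverse placement.
    """
    ho, wo = occ.height, occ.width
    hd, wd = occder.height, occder.width

    if alpha % 2 == 0:
        # Corner overlap in both axes.
        w_b = int(round(wo * beta))
        h_b = int(round(ho * beta))
        w_b = min(max(w_b, 1), min(wo, wd))
        h_b = min(max(h_b, 1), min(ho, hd))
        hs, ws = ho + hd - h_b, wo + wd - w_b
        if alpha == 2:  # occluder top-right
            occ_yx, occder_yx = (hd - h_b, 0), (0, wo - w_b)
        elif alpha == 4:  # top-left
            occ_yx, occder_yx = (hd - h_b, ws - wo), (0, 0)
        elif alpha == 6:  # bottom-left
            occ_yx, occder_yx = (0, ws - wo), (hs - hd, 0)
        else:  # alpha == 8, bottom-right
            occ_yx, occder_yx = (0, 0), (hs - hd, wo - w_b)
        return (hs, ws), occ_yx, occder_yx

    # Cardinal overlap along one axis; transverse placement centred with
    # +/-10% jitter of the transverse extent.
    if alpha in (1, 5):  # occluder right / left
        w_b = min(max(int(round(wo * beta)), 1), min(wo, wd))
        ws = wo + wd - w_b
        jitter = int(round(rng.uniform(-0.1, 0.1) * ho))
        dy = (ho - hd) // 2 + jitter
        y_occ, y_occder = (0, dy) if dy >= 0 else (-dy, 0)
        hs = max(y_occ + ho, y_occder + hd)
        if alpha == 1:
            return (hs, ws), (y_occ, 0), (y_occder, wo - w_b)
        return (hs, ws), (y_occ, ws - wo), (y_occder, 0)

    # alpha in (3, 7): occluder above / below
    h_b = min(max(int(round(ho * beta)), 1), min(ho, hd))
    hs = ho + hd - h_b
    jitter = int(round(rng.uniform(-0.1, 0.1) * wo))
    dx = (wo - wd) // 2 + jitter
    x_occ, x_occder = (0, dx) if dx >= 0 else (-dx, 0)
    ws = max(x_occ + wo, x_occder + wd)
    if alpha == 3:
        return (hs, ws), (hd - h_b, x_occ), (0, x_occder)
    return (hs, ws), (0, x_occ), (hs - hd, x_occder)


def _compose(
    occ: PoolItem,
    occder: PoolItem,
    layout: tuple[tuple[int, int], tuple[int, int], tuple[int, int]],
    gamma: bool,
    case_alpha: int,
    beta: float,
) -> SynthesisSample:
    (hs, ws), occ_yx, occder_yx = layout
    i1 = np.zeros((hs, ws, 3), dtype=np.uint8)  # occluded instance canvas
    i2 = np.zeros((hs, ws, 3), dtype=np.uint8)  # occluder instance canvas
    _paste(i1, occ, *occ_yx)
    _paste(i2, occder, *occder_yx)
    m_occluder_canvas = _canvas_mask(i2)

    if not gamma:
        i_occ = i1.copy()
        i_occ[m_occluder_canvas] = 0
        i_intact = i1
        i_occder = i2
    else:
        # Reverse synthesis: the untouched occluder is both the "occluded"
        # input and the target (an identity mapping); the erased occluded
        # instance plays the occluder role.
        i_occ = i2
        i_intact = i2.copy()
        i_occder = i1.copy()
        i_occder[m_occluder_canvas] = 0

    m_occ = _canvas_mask(i_occ)
    m_occder = _canvas_mask(i_occder)
    m_intact = _canvas_mask(i_intact)
    eps = occlusion_rate(
        _canvas_mask(i_occ if not gamma else i_occder),
        _canvas_mask(i1),
    )
    return SynthesisSample(
        i_occ, i_occder, i_intact, m_occ, m_occder, m_intact,
        case_alpha, beta, gamma, eps,
        occ_hw=(occ.height, occ.width), occder_hw=(occder.height, occder.width),
    )


def synthesize_pair(
    pool: InstancePool | Sequence[PoolItem],
    case_alpha: int | None = None,
    beta: float | None = None,
    gamma: bool | None = None,
    rng_seed: int | np.random.Generator = 0,
    gamma_prob: float = 0.5,
) -> SynthesisSample:
    """Draw one overlapping-cover sample from the instance pool.

    Unspecified parameters are drawn from the seeded generator:
    ``case_alpha`` uniform over 1..8, ``beta`` uniform over (0.2, 0.85],
    ``gamma`` Bernoulli(``gamma_prob``).  Occluders failing the size filter
    are rejection-sampled; pastes with occlusion rate <= 0.1 bump ``beta``
    by 0.05 (capped at 0.85) and, if still failing, the pair is resampled.
    Deterministic given the seed.
    """
    items = pool.items if isinstance(pool, InstancePool) else list(pool)
    if len(items) < 2:
        raise ValueError("pool must contain at least 2 items")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    if beta is not None and not (BETA_RANGE[0] < beta <= BETA_RANGE[1]):
        raise ValueError(f"beta must lie in ({BETA_RANGE[0]}, {BETA_RANGE[1]}]")
    if case_alpha is not None and case_alpha not in range(1, 9):
        raise ValueError("case_alpha must be in 1..8")

    alpha = case_alpha if case_alpha is not None else int(rng.integers(1, 9))
    g = gamma if gamma is not None else bool(rng.random() < gamma_prob)

    for _ in range(_MAX_PAIR_ATTEMPTS):
        occ = items[int(rng.integers(len(items)))]
        # Rejection-sample an occluder passing the height filter.
        occder = None
        for _ in range(_MAX_PAIR_ATTEMPTS):
            cand = items[int(rng.integers(len(items)))]
            if cand is not occ and size_match(occ.height, cand.height):
                occder = cand
                break
        if occder is None:
            continue
        b = beta if beta is not None else float(
            rng.uniform(BETA_RANGE[0], BETA_RANGE[1])
        )
        while True:
            layout = _case_layout(alpha, occ, occder, b, rng)
            sample = _compose(occ, occder, layout, g, alpha, b)
            if sample.epsilon > MIN_OCCLUSION_RATE:
                return sample
            if b >= BETA_RANGE[1]:
                break  # resample the pair
            b = min(BETA_RANGE[1], b + 0.05)
    raise RuntimeError(
        "instance pool exhausted: no pair satisfied the size and "
        "occlusion-rate filters"
    )


def random_cover(
    pool: InstancePool | Sequence[PoolItem],
    rng_seed: int | np.random.Generator = 0,
    gamma: bool = False,
) -> SynthesisSample:
    """Baseline: paste the occluder at a uniform offset with box overlap.

    No size filter, no occlusion-rate filter, no directional case.  Shares
    the output contract of :func:`synthesize_pair` (``case_alpha`` is 0).
    """
    items = pool.items if isinstance(pool, InstancePool) else list(pool)
    if len(items) < 2:
        raise ValueError("pool must contain at least 2 items")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    for _ in range(_MAX_PAIR_ATTEMPTS):
        i, j = rng.choice(len(items), size=2, replace=False)
        occ, occder = items[int(i)], items[int(j)]
        # Offset of the occluder's origin relative to the occluded one's,
        # uniform over all placements with intersecting bounding boxes.
        dy = int(rng.integers(-occder.height + 1, occ.height))
        dx = int(rng.integers(-occder.width + 1, occ.width))
        y_occ, y_der = max(0, -dy), max(0, dy)
        x_occ, x_der = max(0, -dx), max(0, dx)
        hs = max(y_occ + occ.height, y_der + occder.height)
        ws = max(x_occ + occ.width, x_der + occder.width)
        layout = ((hs, ws), (y_occ, x_occ), (y_der, x_der))
        sample = _compose(occ, occder, layout, gamma, 0, float("nan"))
        if np.any(sample.m_intact):
            return sample
    raise RuntimeError("random_cover failed to produce a sample")


def build_pool(
    images: Sequence[np.ndarray],
    annotations: Sequence[Sequence[tuple[float, float]] | dict],
    image_index: Sequence[int] | None = None,
) -> InstancePool:
    """Rasterize complete-instance polygons into a tight-cropped pool.

    ``annotations`` is a sequence of polygons (lists of (x, y) vertices) or
    dicts with a ``"points"`` key; ``image_index[i]`` says which image the
    i-th polygon lives on (default: all on image 0).  Degenerate polygons
    (fewer than 3 vertices or zero rasterized area) are skipped with a
    warning.
    """
    import warnings

    from skimage.draw import polygon as draw_polygon

    pool = InstancePool()
    for i, ann in enumerate(annotations):
        pts = ann["points"] if isinstance(ann, dict) else ann
        img = images[image_index[i] if image_index is not None else 0]
        if len(pts) < 3:
            warnings.warn(f"skipping degenerate polygon #{i} (<3 vertices)")
            continue
        xs = np.asarray([p[0] for p in pts], dtype=float)
        ys = np.asarray([p[1] for p in pts], dtype=float)
        rr, cc = draw_polygon(ys, xs, shape=img.shape[:2])
        if rr.size == 0:
            warnings.warn(f"skipping degenerate polygon #{i} (zero area)")
            continue
        mask = np.zeros(img.shape[:2], dtype=bool)
        mask[rr, cc] = True
        box = mask_bbox(mask)
        crop_mask = box.crop(mask)
        crop_rgb = box.crop(img).copy()
        crop_rgb[~crop_mask] = 0
        pool.items.append(PoolItem(crop_rgb, crop_mask))
    return pool


def letterbox_sample(sample: SynthesisSample, size: int) -> SynthesisSample:
    """Pad a sample's rasters to square (centred) and resize to ``size``.

    Preserves aspect ratio; masks go through the binarizing resize, images
    through plain bilinear resampling.
    """
    h, w = sample.m_intact.shape
    side = max(h, w)
    py, px = (side - h) // 2, (side - w) // 2

    def pad_resize_mask(m: np.ndarray) -> np.ndarray:
        sq = np.zeros((side, side), dtype=bool)
        sq[py : py + h, px : px + w] = m
        return resize_mask(sq, size, size)

    def pad_resize_img(img: np.ndarray) -> np.ndarray:
        sq = np.zeros((side, side, 3), dtype=np.float64)
        sq[py : py + h, px : px + w] = img
        out = np.stack(
            [resize_bilinear(sq[..., c], size, size) for c in range(3)], axis=-1
        )
        return np.clip(out, 0, 255).astype(np.uint8)

    m_intact = pad_resize_mask(sample.m_intact)
    m_occder = pad_resize_mask(sample.m_occder)
    # Re-derive the visible mask so the m_occ = m_intact AND NOT m_occder
    # algebra survives the independent resampling of the other two masks.
    m_occ = m_intact & ~m_occder
    return SynthesisSample(
        pad_resize_img(sample.i_occ),
        pad_resize_img(sample.i_occder),
        pad_resize_img(sample.i_intact),
        m_occ,
        m_occder,
        m_intact,
        sample.case_alpha,
        sample.beta,
        sample.gamma,
        sample.epsilon,
        occ_hw=sample.occ_hw,
        occder_hw=sample.occder_hw,
    )


def synthesis_stream(
    pool: InstancePool,
    strategy: str = "overlap",
    gamma_prob: float = 0.5,
    seed: int = 0,
    size: int | None = None,
) -> Iterator[SynthesisSample]:
    """Endless seeded stream of synthesis samples for training loops."""
    if strategy not in ("overlap", "random"):
        raise ValueError("strategy must be 'overlap' or 'random'")
    rng = np.random.default_rng(seed)
    while True:
        if strategy == "overlap":
            s = synthesize_pair(pool, rng_seed=rng, gamma_prob=gamma_prob)
        else:
            g = bool(rng.random() < gamma_prob)
            s = random_cover(pool, rng_seed=rng, gamma=g)
        yield letterbox_sample(s, size) if size is not None else s
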