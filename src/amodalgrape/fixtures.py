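"""Procedural grape-like instance fixtures.

Every trainable or measurable component in this package is exercised on
synthetic data produced here, so the whole pipeline runs with no dataset
download.  A fixture instance is a union of 15–40 jittered circles
("berries") whose centres lie inside an ellipse — an irregular, connected,
cluster-shaped silhouette with a per-berry shaded RGB patch.  A fixture
scene places several such instances with a known depth order, giving exact
ground truth for visible masks, amodal (complete) masks, and the
occluder→occludee edge list.

What this emulates — and what it does not: the generator reproduces the
*geometry* of cluster occlusion (lobed contours, partial overlap, depth
layering).  It does not emulate photometric nuisance factors of field
imagery (lighting, leaf clutter, motion blur), so tests passing on fixtures
validate the algorithms' contracts, not field robustness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from amodalgrape.mask_core import mask_bbox
from amodalgrape.synthesis import InstancePool, PoolItem

__all__ = ["FixtureScene", "make_grape_instance", "make_scene", "pool_from_fixtures"]


@dataclass
class FixtureScene:
    """A multi-instance scene with exact occlusion ground truth.

    ``label_map`` holds visible pixels (0 background, k >= 1 instance id);
    ``amodal_masks[k-1]`` / ``visible_masks[k-1]`` are instance k's complete
    and visible silhouettes; ``occlusion_edges`` lists (occluder_id,
    occludee_id) pairs with nonempty hidden area.  Depth order equals
    placement order: later instances paint over earlier ones.
    """

    label_map: np.ndarray
    amodal_masks: list[np.ndarray] = field(default_factory=list)
    visible_masks: list[np.ndarray] = field(default_factory=list)
    occlusion_edges: list[tuple[int, int]] = field(default_factory=list)
    rgb: np.ndarray | None = None
    rng_seed: int = 0


def make_grape_instance(
    rng_seed: int | np.random.Generator, scale: int = 48
) -> tuple[np.ndarray, np.ndarray]:
    """One cluster-shaped instance: (mask, rgb) tight-cropped to the mask.

    ``scale`` sets the nominal cluster diameter in pixels (>= 16).  The
    silhouette is the largest connected component of a union of 15–40
    circles with radii around ``scale / 6``, centres inside an ellipse.
    """
    if scale < 16:
        raise ValueError("scale must be >= 16")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    side = int(scale * 1.5)
    canvas = np.zeros((side, side), dtype=bool)
    rgb = np.zeros((side, side, 3), dtype=np.uint8)
    yy, xx = np.mgrid[0:side, 0:side]
    cy, cx = side / 2, side / 2
    # Slightly prolate ellipse: clusters hang longer than they are wide.
    a, b = scale * 0.46, scale * 0.58
    n_berries = int(rng.integers(15, 41))
    base_hue = rng.uniform(0.25, 0.45)  # greenish
    for _ in range(n_berries):
        # Rejection-sample a centre inside the ellipse.
        while True:
            dx = rng.uniform(-a, a)
            dy = rng.uniform(-b, b)
            if (dx / a) ** 2 + (dy / b) ** 2 <= 1.0:
                break
        r = scale / 6 * rng.uniform(0.65, 1.25)
        berry = (yy - (cy + dy)) ** 2 + (xx - (cx + dx)) ** 2 <= r**2
        shade = rng.uniform(0.55, 1.0)
        color = np.array(
            [90 * base_hue * shade + 30, 160 * shade + 40, 60 * shade + 20]
        )
        rgb[berry & ~canvas] = np.clip(color, 1, 255).astype(np.uint8)
        canvas |= berry
    labels, n = ndimage.label(canvas)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        canvas = labels == keep
        rgb[~canvas] = 0
    box = mask_bbox(canvas)
    return box.crop(canvas).copy(), box.crop(rgb).copy()


def make_scene(
    n_instances: int,
    overlap_fraction: float = 0.5,
    rng_seed: int = 0,
    canvas_hw: tuple[int, int] = (160, 160),
    scale: int = 48,
    clear_margin: int = 5,
) -> FixtureScene:
    """Compose a depth-ordered scene of cluster instances.

    Each instance after the first overlaps a previously placed one with
    probability ``overlap_fraction`` (placed near it); otherwise it is
    dropped at a clear spot at least ``clear_margin`` pixels away from
    every earlier instance (so "not overlapping" also means "not within
    the pair-sampling offset of another instance"); if the canvas is too
    crowded for any clear spot, the instance is placed anyway and the
    overlap is recorded in the edge list.  All amodal masks, visible masks
    and occlusion edges are recorded exactly.
    """
    if n_instances < 1:
        raise ValueError("n_instances must be >= 1")
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    H, W = canvas_hw
    label_map = np.zeros((H, W), dtype=np.int32)
    scene_rgb = np.zeros((H, W, 3), dtype=np.uint8)
    amodal: list[np.ndarray] = []
    occupied = np.zeros((H, W), dtype=bool)
    # Union of earlier instances dilated by the clear margin; used to keep
    # non-overlapping placements genuinely separated.
    blocked = np.zeros((H, W), dtype=bool)
    dilate = ndimage.generate_binary_structure(2, 2)

    for k in range(1, n_instances + 1):
        mask, rgb = make_grape_instance(rng, scale=scale)
        h, w = mask.shape
        h, w = min(h, H), min(w, W)
        mask, rgb = mask[:h, :w], rgb[:h, :w]
        want_overlap = k > 1 and rng.random() < overlap_fraction
        y = x = 0
        placed = False
        for _ in range(80):
            if want_overlap:
                # Land near a previous instance's centre.
                prev = amodal[int(rng.integers(len(amodal)))]
                ys, xs = np.nonzero(prev)
                cy, cx = float(ys.mean()), float(xs.mean())
                y = int(np.clip(cy - h / 2 + rng.uniform(-h / 3, h / 3), 0, H - h))
                x = int(np.clip(cx - w / 2 + rng.uniform(-w / 3, w / 3), 0, W - w))
            else:
                y = int(rng.integers(0, H - h + 1))
                x = int(rng.integers(0, W - w + 1))
            full = np.zeros((H, W), dtype=bool)
            full[y : y + h, x : x + w] = mask
            if want_overlap:
                ok = np.any(full & occupied)
            else:
                ok = not np.any(full & blocked)
            if ok:
                placed = True
                break
        if not placed and not want_overlap:
            # Random search failed: scan a coarse grid for any clear spot.
            for gy in range(0, H - h + 1, 4):
                for gx in range(0, W - w + 1, 4):
                    cand = np.zeros((H, W), dtype=bool)
                    cand[gy : gy + h, gx : gx + w] = mask
                    if not np.any(cand & blocked):
                        y, x, placed = gy, gx, True
                        break
                if placed:
                    break
        full = np.zeros((H, W), dtype=bool)
        full[y : y + h, x : x + w] = mask
        amodal.append(full)
        occupied |= full
        blocked |= ndimage.binary_dilation(full, dilate, iterations=clear_margin)
        label_map[full] = k
        patch = scene_rgb[y : y + h, x : x + w]
        patch[mask] = rgb[mask]

    visible = [label_map == k for k in range(1, n_instances + 1)]
    edges = []
    for k in range(1, n_instances + 1):
        for j in range(k + 1, n_instances + 1):
            # j was placed after k, so j occludes k where their masks meet.
            hidden = amodal[k - 1] & visible[j - 1]
            if np.any(hidden):
                edges.append((j, k))
    return FixtureScene(label_map, amodal, visible, edges, scene_rgb, int(rng_seed))


def pool_from_fixtures(
    n_items: int, rng_seed: int = 0, scale: int = 48
) -> InstancePool:
    """An instance pool of procedural clusters for synthesis experiments."""
    rng = np.random.default_rng(rng_seed)
    pool = InstancePool()
    for _ in range(n_items):
        mask, rgb = make_grape_instance(rng, scale=scale)
        pool.items.append(PoolItem(rgb, mask))
    return pool
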