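"""Shared fixtures and independent oracles for the test suite.

The oracle functions here are deliberately written as straight-line,
per-pixel implementations, independent of the vectorized code paths they
check.
"""

from __future__ import annotations

import numpy as np
import pytest

from amodalgrape.fixtures import pool_from_fixtures

# Ties at 0.5 count as foreground; the slack keeps the rule stable under
# reordered float summation (same constant as the implementation contract).
BIN_THRESHOLD = 0.5 - 1e-9


def oracle_bilinear(img: np.ndarray, th: int, tw: int) -> np.ndarray:
    """Per-pixel bilinear resample at output pixel centers, edge-clamped."""
    img = np.asarray(img, dtype=np.float64)
    h, w = img.shape
    out = np.zeros((th, tw))
    for oy in range(th):
        for ox in range(tw):
            sy = (oy + 0.5) * h / th - 0.5
            sx = (ox + 0.5) * w / tw - 0.5
            y0 = int(np.floor(sy))
            x0 = int(np.floor(sx))
            ty = sy - y0
            tx = sx - x0
            val = 0.0
            for dy, wy in ((0, 1 - ty), (1, ty)):
                for dx, wx in ((0, 1 - tx), (1, tx)):
                    yy = min(max(y0 + dy, 0), h - 1)
                    xx = min(max(x0 + dx, 0), w - 1)
                    val += wy * wx * img[yy, xx]
            out[oy, ox] = val
    return out


def oracle_resize_mask(m: np.ndarray, th: int, tw: int) -> np.ndarray:
    if m.shape == (th, tw):
        return m.astype(bool).copy()
    return oracle_bilinear(m.astype(float), th, tw) >= BIN_THRESHOLD


def oracle_incoherent_mask(m: np.ndarray, dh: int, dw: int) -> np.ndarray:
    """Straight-line D(m XOR U(D(m))) using the per-pixel resize oracle.

    Mask resizes binarize at 0.5 (ties to foreground); the final
    downsample of the difference ribbon keeps any pixel with nonzero lost
    coverage, matching the documented construction.
    """
    m = m.astype(bool)
    down = oracle_resize_mask(m, dh, dw)
    up = oracle_resize_mask(down, *m.shape)
    return oracle_bilinear((m ^ up).astype(float), dh, dw) > 1e-9


def oracle_inner_band(x: np.ndarray, d: float) -> np.ndarray:
    """Exhaustive Euclidean distance band: pixels of x within d of any
    background pixel, the outside of the image counting as background."""
    x = x.astype(bool)
    h, w = x.shape
    bg = np.argwhere(~x)
    band = np.zeros_like(x)
    for y, px in np.argwhere(x):
        # Distance to out-of-image background.
        dist = min(y + 1, x.shape[0] - y, px + 1, x.shape[1] - px)
        if bg.size:
            dist = min(dist, np.sqrt(((bg - (y, px)) ** 2).sum(axis=1)).min())
        if dist <= d:
            band[y, px] = True
    return band


def oracle_boundary_iou(g: np.ndarray, p: np.ndarray, d: float) -> float:
    gb = oracle_inner_band(g, d)
    pb = oracle_inner_band(p, d)
    union = np.count_nonzero(gb | pb)
    if union == 0:
        return 1.0
    return np.count_nonzero(gb & pb) / union


def oracle_bce(p: np.ndarray, t: np.ndarray) -> float:
    """Per-pixel summed BCE with the clamped-probability convention."""
    total = 0.0
    pf, tf = p.ravel(), t.ravel()
    for pi, ti in zip(pf, tf):
        pc = min(max(pi, 1e-7), 1 - 1e-7)
        total += -(ti * np.log(pc) + (1 - ti) * np.log(1 - pc))
    return total / pf.size


def oracle_dice(p: np.ndarray, t: np.ndarray) -> float:
    num = 2 * float((p * t).sum()) + 1.0
    den = float((p**2).sum()) + float((t**2).sum()) + 1.0
    return 1.0 - num / den


@pytest.fixture(scope="session")
def small_pool():
    """A deterministic pool of 12 procedural cluster instances."""
    return pool_from_fixtures(12, rng_seed=42, scale=36)


def random_blob_mask(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """A random smooth-ish blob mask (possibly empty)."""
    field = rng.random((h, w))
    from scipy import ndimage

    smooth = ndimage.uniform_filter(field, size=max(2, min(h, w) // 4))
    return smooth > np.quantile(smooth, rng.uniform(0.4, 0.8))
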