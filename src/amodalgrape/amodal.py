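"""Amodal mask completion and occlusion-relation inference.

The completer is a U-Net that consumes two binary mask channels — the
visible mask of the occluded instance and the mask of its occluder — and
predicts the occluded instance's complete silhouette.  It operates on
masks only: the occluded content has to be *hallucinated* from shape
context, and the occluder channel tells the network where hidden content
may legally appear.

The training loss weights the two regions differently: BCE restricted to
the occluder region (where completion happens) plus ``lambda2`` times BCE
on its complement (where the prediction must simply copy the visible
input); ``lambda2`` defaults to 5.

Once a completer is trained, the *occlusion relation* between two
segmented instances is decided by cross-prediction: complete i against j
and j against i, and compare the relative area growths ``delta = (|Ma| -
|M|) / |M|``.  The instance that grows more is the occluded one; if
neither grows beyond a small tolerance the pair does not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterable, Iterator

import numpy as np
from sklearn.base import BaseEstimator

from amodalgrape.mask_core import as_mask, mask_bbox
from amodalgrape.nn import Adam, Conv2d, ConvTranspose2d, Module, Sequential, Tensor, bce_loss, concat
from amodalgrape.nn.layers import warmup_cosine_lr
from amodalgrape.synthesis import SynthesisSample

__all__ = [
    "AmodalPrediction",
    "OcclusionRelation",
    "UNet",
    "AmodalCompleter",
    "amodal_loss",
    "train_amodal",
    "occlusion_relation",
    "pair_instances",
]


@dataclass
class AmodalPrediction:
    """Probability grid and its 0.5-thresholded binary mask."""

    p_a: np.ndarray
    m_a: np.ndarray


@dataclass
class OcclusionRelation:
    """Outcome of the cross-prediction rule for an instance pair.

    ``o`` is -1 (no overlap), 1 (the second instance occludes the first)
    or 0 (the reverse); ``ambiguous`` flags an exact tie of the two area
    growths above the tolerance, reported as 0.
    """

    o: int
    delta_i: float
    delta_j: float
    ambiguous: bool = False


def amodal_loss(
    p_a, m_intact: np.ndarray, m_occder: np.ndarray, lambda2: float = 5.0
) -> float | Tensor:
    """Region-weighted BCE for mask completion.

    BCE of prediction vs intact target restricted to the occluder region,
    plus ``lambda2`` times the BCE restricted to its complement.  Accepts a
    plain array (returns float) or an autodiff tensor (returns the loss
    node).
    """
    if lambda2 < 0:
        raise ValueError("lambda2 must be >= 0")
    t = np.asarray(m_intact, dtype=np.float64)
    occ = np.asarray(m_occder, dtype=np.float64)
    pt = p_a if isinstance(p_a, Tensor) else Tensor(np.asarray(p_a, dtype=np.float64))
    if pt.data.shape != t.shape or pt.data.shape != occ.shape:
        raise ValueError("shape mismatch")
    loss = bce_loss(pt, t, weight=occ) + lambda2 * bce_loss(pt, t, weight=1.0 - occ)
    return loss if isinstance(p_a, Tensor) else float(loss.data)


class UNet(Module):
    """Encoder–decoder with skip connections on 2-channel mask input."""

    def __init__(
        self, depth: int = 4, base_width: int = 32, rng: np.random.Generator | None = None
    ):
        rng = rng or np.random.default_rng(0)
        self.depth = depth
        widths = [base_width * 2**i for i in range(depth + 1)]
        self.enc_blocks = []
        self.down = []
        c_in = 2
        for d in range(depth):
            self.enc_blocks.append(
                Sequential(Conv2d(c_in, widths[d], rng=rng), Conv2d(widths[d], widths[d], rng=rng))
            )
            self.down.append(Conv2d(widths[d], widths[d + 1], stride=2, rng=rng))
            c_in = widths[d + 1]
        self.bottleneck = Sequential(
            Conv2d(widths[depth], widths[depth], rng=rng),
            Conv2d(widths[depth], widths[depth], rng=rng),
        )
        self.up = []
        self.dec_blocks = []
        for d in reversed(range(depth)):
            self.up.append(ConvTranspose2d(widths[d + 1], widths[d], rng=rng))
            self.dec_blocks.append(
                Sequential(
                    Conv2d(2 * widths[d], widths[d], rng=rng),
                    Conv2d(widths[d], widths[d], rng=rng),
                )
            )
        self.head = Conv2d(base_width, 1, k=1, pad=0, relu=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        skips = []
        for enc, down in zip(self.enc_blocks, self.down):
            x = enc(x)
            skips.append(x)
            x = down(x)
        x = self.bottleneck(x)
        for up, dec, skip in zip(self.up, self.dec_blocks, reversed(skips)):
            x = up(x)
            x = dec(concat([x, skip]))
        return self.head(x).sigmoid()


class AmodalCompleter(BaseEstimator):
    """U-Net mask completer with an sklearn estimator interface.

    ``fit`` consumes synthesis samples (a list, or an endless iterator such
    as :func:`amodalgrape.synthesis.synthesis_stream`); every sample is
    letterboxed upstream to ``input_size``.  ``predict`` maps a (visible,
    occluder) mask pair to the completed amodal mask.

    Defaults mirror a full-scale training recipe (320 px input, depth-4
    width-32 U-Net, Adam lr 1e-4 with beta1 0.9 and weight decay 5e-4,
    batch 16, 15000 iterations); tests and desk-scale studies override
    them.  Deterministic given ``seed``.
    """

    def __init__(
        self,
        input_size: int = 320,
        depth: int = 4,
        base_width: int = 32,
        lr: float = 1e-4,
        beta1: float = 0.9,
        weight_decay: float = 5e-4,
        lambda2: float = 5.0,
        batch_size: int = 16,
        n_iters: int = 15000,
        seed: int = 0,
        threshold: float = 0.5,
        lr_schedule: bool = True,
    ):
        self.input_size = input_size
        self.depth = depth
        self.base_width = base_width
        self.lr = lr
        self.beta1 = beta1
        self.weight_decay = weight_decay
        self.lambda2 = lambda2
        self.batch_size = batch_size
        self.n_iters = n_iters
        self.seed = seed
        self.threshold = threshold
        self.lr_schedule = lr_schedule

    def _sample_to_xy(self, s: SynthesisSample) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if s.m_intact.shape != (self.input_size, self.input_size):
            raise ValueError(
                f"sample size {s.m_intact.shape} does not match input_size "
                f"{self.input_size}; letterbox samples first"
            )
        x = np.stack([s.m_occ, s.m_occder]).astype(np.float32)
        return x, s.m_intact.astype(np.float32), s.m_occder.astype(np.float32)

    def fit(self, X: Iterable[SynthesisSample], y=None) -> "AmodalCompleter":
        rng = np.random.default_rng(self.seed)
        self.net_ = UNet(self.depth, self.base_width, rng=rng)
        opt = Adam(
            self.net_.parameters(),
            lr=self.lr,
            beta1=self.beta1,
            weight_decay=self.weight_decay,
        )
        if isinstance(X, (list, tuple)):
            pool = list(X)
            if not pool:
                raise ValueError("empty sample stream")

            def draw() -> SynthesisSample:
                return pool[int(rng.integers(len(pool)))]

        else:
            it: Iterator[SynthesisSample] = iter(X)

            def draw() -> SynthesisSample:
                try:
                    return next(it)
                except StopIteration:
                    raise ValueError("empty or exhausted sample stream") from None

        self.loss_history_ = []
        for step in range(self.n_iters):
            xs, ys, occs = [], [], []
            for _ in range(self.batch_size):
                x, t, occ = self._sample_to_xy(draw())
                xs.append(x)
                ys.append(t)
                occs.append(occ)
            xb = Tensor(np.stack(xs))
            p = self.net_(xb)
            loss = amodal_loss(
                p,
                np.stack(ys)[:, None],
                np.stack(occs)[:, None],
                self.lambda2,
            )
            opt.zero_grad()
            loss.backward()
            lr = (
                warmup_cosine_lr(self.lr, step, self.n_iters)
                if self.lr_schedule
                else self.lr
            )
            opt.step(lr=lr)
            self.loss_history_.append(float(loss.data))
        self.n_iter_ = self.n_iters
        return self

    def predict(self, m_occ: np.ndarray, m_occder: np.ndarray) -> AmodalPrediction:
        """Complete the visible mask given its occluder's mask."""
        if not hasattr(self, "net_"):
            raise ValueError("completer is not fitted")
        m_occ, m_occder = as_mask(m_occ), as_mask(m_occder)
        if m_occ.shape != m_occder.shape:
            raise ValueError("shape mismatch")
        if m_occ.shape != (self.input_size, self.input_size):
            raise ValueError(
                f"input must be {self.input_size}px square, got {m_occ.shape}"
            )
        x = Tensor(np.stack([m_occ, m_occder]).astype(np.float32)[None])
        p = self.net_(x).data[0, 0]
        return AmodalPrediction(p_a=p, m_a=p >= self.threshold)


def train_amodal(samples: Iterable[SynthesisSample], **params) -> AmodalCompleter:
    """Fit an :class:`AmodalCompleter` on a sample stream (thin wrapper)."""
    return AmodalCompleter(**params).fit(samples)


def _complete(completer, m_a: np.ndarray, m_b: np.ndarray) -> np.ndarray:
    if hasattr(completer, "predict"):
        return completer.predict(m_a, m_b).m_a
    return as_mask(completer(m_a, m_b))


def occlusion_relation(
    m_i: np.ndarray,
    m_j: np.ndarray,
    completer: AmodalCompleter | Callable[[np.ndarray, np.ndarray], np.ndarray],
    tau: float = 0.01,
) -> OcclusionRelation:
    """Cross-prediction occlusion rule for an instance pair.

    Completes i against j and j against i; ``delta = (|Ma| - |M|) / |M|``
    measures each instance's area growth.  Both growths at or below ``tau``
    means no occlusion (-1); otherwise the instance with the larger growth
    is the occluded one (1 when i grew more, i.e. j occludes i; 0 for the
    reverse).  An exact tie above ``tau`` is reported as 0 with
    ``ambiguous=True``.

    ``completer`` is either a fitted :class:`AmodalCompleter` or any
    callable mapping (visible, occluder) masks to an amodal mask — e.g. a
    ground-truth oracle in tests.
    """
    m_i, m_j = as_mask(m_i), as_mask(m_j)
    if not np.any(m_i) or not np.any(m_j):
        raise ValueError("instance masks must be nonempty")
    ma_i = _complete(completer, m_i, m_j)
    ma_j = _complete(completer, m_j, m_i)
    delta_i = (np.count_nonzero(ma_i) - np.count_nonzero(m_i)) / np.count_nonzero(m_i)
    delta_j = (np.count_nonzero(ma_j) - np.count_nonzero(m_j)) / np.count_nonzero(m_j)
    if delta_i <= tau and delta_j <= tau:
        return OcclusionRelation(-1, delta_i, delta_j)
    if delta_i > delta_j:
        return OcclusionRelation(1, delta_i, delta_j)
    if delta_j > delta_i:
        return OcclusionRelation(0, delta_i, delta_j)
    return OcclusionRelation(0, delta_i, delta_j, ambiguous=True)


def pair_instances(masks: list[np.ndarray]) -> list[tuple[int, int]]:
    """All unordered index pairs whose tight bounding boxes intersect."""
    if not masks:
        raise ValueError("need at least one mask")
    boxes = [mask_bbox(m) for m in masks]
    pairs = []
    for (i, bi), (j, bj) in combinations(enumerate(boxes), 2):
        if bi is not None and bj is not None and bi.intersects(bj):
            pairs.append((i, j))
    return pairs
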