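"""Dual-decoder segmentation heads with pixel affinity learning.

The instance-segmentation model carries two per-proposal decoders on top of
ROI-aligned features: a *mask decoder* (14x14 ROI, 28x28 output) predicting
the instance silhouette, and an *incoherent-region decoder* (28x28 ROI,
28 or 56 output) predicting the pixels that a size transformation corrupts.
A pixel affinity learning module (PALM) couples the two streams at two
scales so their predictions stay consistent: the concatenated features pass
through a bottleneck mapping, a two-way softmax reweights each branch per
position and channel, and a squeeze-and-excitation block over the shared
representation is added back to both branches.

Losses: plain BCE for the mask decoder; dice+BCE for the incoherent
decoder plus a lambda-weighted dice+BCE term restricted to the local
(overlap-only) incoherent region.  A boundary-supervised baseline swaps the
incoherent targets for thin Laplacian boundary masks, leaving every tensor
contract unchanged.

The backbone / RPN / box head of a full two-stage detector are *not*
re-implemented here; the heads consume ROI features from a pluggable
provider (a small convolutional encoder over ground-truth-jittered
proposal crops in the training harness).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from amodalgrape.incoherent import build_supervision_triple
from amodalgrape.mask_core import BBox, laplacian_boundary, mask_bbox, resize_bilinear, resize_mask
from amodalgrape.nn import SE, Adam, Conv2d, ConvTranspose2d, Module, Tensor, bce_loss, concat, dice_loss
from amodalgrape.nn.layers import warmup_cosine_lr

__all__ = [
    "FeaturePair",
    "HeadConfig",
    "HeadPrediction",
    "PALM",
    "palm_forward",
    "DualDecoderHead",
    "mask_loss",
    "incoherent_loss",
]


@dataclass
class FeaturePair:
    """Two same-shape NCHW feature grids, one per decoder branch."""

    f_m: Tensor
    f_i: Tensor

    def __post_init__(self) -> None:
        if not isinstance(self.f_m, Tensor):
            self.f_m = Tensor(self.f_m)
        if not isinstance(self.f_i, Tensor):
            self.f_i = Tensor(self.f_i)
        if self.f_m.shape != self.f_i.shape:
            raise ValueError(
                f"branch shapes differ: {self.f_m.shape} vs {self.f_i.shape}"
            )


@dataclass
class HeadConfig:
    """Architecture and supervision switches of the dual-decoder heads."""

    mask_roi: int = 14
    inc_roi: int = 28
    mask_out: int = 28
    inc_out: int = 56
    use_palm: bool = True
    supervision: str = "incoherent"  # or "boundary"
    lambda_inc: float = 2.0
    channels: int = 16
    n_refine: int = 2

    def __post_init__(self) -> None:
        if self.inc_out not in (28, 56):
            raise ValueError("inc_out must be 28 or 56")
        if self.mask_out != 2 * self.mask_roi:
            raise ValueError("mask_out must equal 2 * mask_roi")
        if self.supervision not in ("incoherent", "boundary"):
            raise ValueError("supervision must be 'incoherent' or 'boundary'")


@dataclass
class HeadPrediction:
    """Per-proposal probability grids from the two decoders."""

    p_m: np.ndarray
    p_i: np.ndarray
    t_m: Tensor | None = field(default=None, repr=False)
    t_i: Tensor | None = field(default=None, repr=False)


class PALM(Module):
    """Pixel affinity learning module coupling the two decoder branches.

    Inputs and outputs are same-shape feature pairs; the last computed
    softmax weight pair is kept on ``last_weights`` for inspection (the two
    grids sum to one at every position and channel).
    """

    def __init__(self, c: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.c = c
        self.phi_down = Conv2d(2 * c, c, rng=rng)
        self.phi_up = Conv2d(c, 2 * c, relu=False, rng=rng)
        self.reduce = Conv2d(2 * c, c, rng=rng)
        self.se = SE(c, rng=rng)
        self.last_weights: tuple[np.ndarray, np.ndarray] | None = None

    def forward(self, pair: FeaturePair) -> FeaturePair:
        fm, fi = pair.f_m, pair.f_i
        c = fm.shape[1]
        if c != self.c:
            raise ValueError(f"expected {self.c} channels, got {c}")
        f = self.phi_up(self.phi_down(concat([fm, fi])))
        f1 = f[:, :c]
        f2 = f[:, c:]
        # Two-way softmax across the branches, per position and channel.
        w1 = (f1 - f2).sigmoid()
        w2 = (f2 - f1).sigmoid()
        self.last_weights = (w1.data.copy(), w2.data.copy())
        fs = self.reduce(concat([fm * w1, fi * w2]))
        shared = self.se(fs)
        return FeaturePair(shared + fm, shared + fi)


def palm_forward(
    pair: FeaturePair, palm: PALM | None = None, rng_seed: int = 0
) -> FeaturePair:
    """Apply a PALM block (a fresh randomly initialized one by default)."""
    if palm is None:
        palm = PALM(int(pair.f_m.shape[1]), rng=np.random.default_rng(rng_seed))
    return palm(pair)


# -- losses -------------------------------------------------------------


def _to_prob_tensor(p) -> Tensor:
    t = p if isinstance(p, Tensor) else Tensor(np.asarray(p, dtype=np.float64))
    return t


def mask_loss(p_m, mpc: np.ndarray) -> float | Tensor:
    """Mean BCE between the mask-decoder probabilities and the target.

    Accepts a plain array (returns a float) or an autodiff tensor (returns
    the loss tensor for training).
    """
    t = np.asarray(mpc, dtype=np.float64)
    pt = _to_prob_tensor(p_m)
    if pt.data.shape != t.shape:
        raise ValueError("shape mismatch")
    loss = bce_loss(pt, t)
    return loss if isinstance(p_m, Tensor) else float(loss.data)


def incoherent_loss(
    p_i, mpi: np.ndarray, minc_oi: np.ndarray, lambda_inc: float = 2.0
) -> float | Tensor:
    """Dice+BCE on the full incoherent target plus a weighted local term.

    The second term restricts the prediction to the local incoherent region
    by elementwise product before comparing against it, weighted by
    ``lambda_inc`` (0 disables it).
    """
    if lambda_inc < 0:
        raise ValueError("lambda_inc must be >= 0")
    t_full = np.asarray(mpi, dtype=np.float64)
    t_loc = np.asarray(minc_oi, dtype=np.float64)
    pt = _to_prob_tensor(p_i)
    if pt.data.shape != t_full.shape or pt.data.shape != t_loc.shape:
        raise ValueError("shape mismatch")
    loss = dice_loss(pt, t_full) + bce_loss(pt, t_full)
    p_loc = pt * Tensor(t_loc)
    loss = loss + lambda_inc * (dice_loss(p_loc, t_loc) + bce_loss(p_loc, t_loc))
    return loss if isinstance(p_i, Tensor) else float(loss.data)


# -- the head network ---------------------------------------------------


class _RoiEncoder(Module):
    """Tiny convolutional feature provider over proposal crops.

    Stands in for the backbone + ROI Align of a full detector: the RGB crop
    of a proposal is resized to the two ROI resolutions and passed through
    shared convolutions to produce c-channel feature grids.
    """

    def __init__(self, c: int, rng: np.random.Generator):
        self.conv1 = Conv2d(3, c, rng=rng)
        self.conv2 = Conv2d(c, c, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv2(self.conv1(x))


class _HeadNet(Module):
    def __init__(self, cfg: HeadConfig, rng: np.random.Generator):
        c = cfg.channels
        self.cfg = cfg
        self.mask_refine = [Conv2d(c, c, rng=rng) for _ in range(cfg.n_refine)]
        self.inc_refine = [Conv2d(c, c, rng=rng) for _ in range(cfg.n_refine)]
        self.mask_up = ConvTranspose2d(c, c, rng=rng)  # 14 -> 28
        self.palm_hi = PALM(c, rng=rng) if cfg.use_palm else None
        self.mask_down = Conv2d(c, c, stride=2, rng=rng)  # 28 -> 14
        self.inc_down = Conv2d(c, c, stride=2, rng=rng)
        self.palm_lo = PALM(c, rng=rng) if cfg.use_palm else None
        self.mask_out_up = ConvTranspose2d(c, c, rng=rng)  # 14 -> 28
        self.inc_out_up1 = ConvTranspose2d(c, c, rng=rng)  # 14 -> 28
        self.inc_out_up2 = (
            ConvTranspose2d(c, c, rng=rng) if cfg.inc_out == 56 else None
        )
        self.mask_logit = Conv2d(c, 1, k=1, pad=0, relu=False, rng=rng)
        self.inc_logit = Conv2d(c, 1, k=1, pad=0, relu=False, rng=rng)

    def forward(self, f_m: Tensor, f_i: Tensor) -> tuple[Tensor, Tensor]:
        cfg = self.cfg
        for layer in self.mask_refine:
            f_m = layer(f_m)
        for layer in self.inc_refine:
            f_i = layer(f_i)
        f_m = self.mask_up(f_m)  # align at inc_roi resolution
        if self.palm_hi is not None:
            pair = self.palm_hi(FeaturePair(f_m, f_i))
            f_m, f_i = pair.f_m, pair.f_i
        f_m = self.mask_down(f_m)
        f_i = self.inc_down(f_i)
        if self.palm_lo is not None:
            pair = self.palm_lo(FeaturePair(f_m, f_i))
            f_m, f_i = pair.f_m, pair.f_i
        f_m = self.mask_out_up(f_m)
        f_i = self.inc_out_up1(f_i)
        if self.inc_out_up2 is not None:
            f_i = self.inc_out_up2(f_i)
        p_m = self.mask_logit(f_m).sigmoid()
        p_i = self.inc_logit(f_i).sigmoid()
        return p_m, p_i


class DualDecoderHead(BaseEstimator):
    """Trainable dual-decoder mask/incoherent heads (sklearn-style).

    ``fit`` consumes fixture scenes: for each instance a jittered proposal
    is drawn, the RGB crop is encoded into ROI features, and the decoders
    are optimized against the supervision triple (or its boundary-mask
    counterpart when ``supervision='boundary'``).

    Fitted attributes: ``net_``, ``encoder_``, ``loss_history_``.
    """

    def __init__(
        self,
        mask_roi: int = 14,
        inc_roi: int = 28,
        mask_out: int = 28,
        inc_out: int = 56,
        use_palm: bool = True,
        supervision: str = "incoherent",
        lambda_inc: float = 2.0,
        channels: int = 16,
        n_refine: int = 2,
        lr: float = 5e-3,
        n_iters: int = 300,
        batch_size: int = 8,
        seed: int = 0,
        lr_schedule: bool = True,
    ):
        self.mask_roi = mask_roi
        self.inc_roi = inc_roi
        self.mask_out = mask_out
        self.inc_out = inc_out
        self.use_palm = use_palm
        self.supervision = supervision
        self.lambda_inc = lambda_inc
        self.channels = channels
        self.n_refine = n_refine
        self.lr = lr
        self.n_iters = n_iters
        self.batch_size = batch_size
        self.seed = seed
        self.lr_schedule = lr_schedule

    def _config(self) -> HeadConfig:
        return HeadConfig(
            mask_roi=self.mask_roi,
            inc_roi=self.inc_roi,
            mask_out=self.mask_out,
            inc_out=self.inc_out,
            use_palm=self.use_palm,
            supervision=self.supervision,
            lambda_inc=self.lambda_inc,
            channels=self.channels,
            n_refine=self.n_refine,
        )

    # -- example preparation -------------------------------------------

    def _boundary_targets(
        self, mpc: np.ndarray, minc_oi: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Boundary-supervision baseline targets at the incoherent size."""
        boundary = laplacian_boundary(resize_mask(mpc, self.inc_out, self.inc_out))
        return boundary, boundary & resize_mask(minc_oi, self.inc_out, self.inc_out)

    def _examples_from_scenes(self, scenes, rng) -> list[dict]:
        examples = []
        for scene in scenes:
            h, w = scene.label_map.shape
            for k, vis in enumerate(scene.visible_masks, start=1):
                box = mask_bbox(vis)
                if box is None:
                    continue
                jx = int(rng.integers(-3, 4))
                jy = int(rng.integers(-3, 4))
                prop = BBox(
                    max(0, box.x0 + jx),
                    max(0, box.y0 + jy),
                    min(w, max(box.x0 + jx + 2, box.x1 + jx)),
                    min(h, max(box.y0 + jy + 2, box.y1 + jy)),
                )
                triple = build_supervision_triple(
                    vis,
                    scene.label_map,
                    prop,
                    mask_out=self.mask_out,
                    inc_out=self.inc_out,
                )
                if triple.degenerate:
                    continue
                mpi, minc_oi = triple.mpi, triple.minc_oi
                if self.supervision == "boundary":
                    mpi, minc_oi = self._boundary_targets(triple.mpc, triple.minc_oi)
                crop = prop.crop(scene.rgb).astype(np.float64) / 255.0
                roi_m = np.stack(
                    [
                        resize_bilinear(crop[..., ch], self.mask_roi, self.mask_roi)
                        for ch in range(3)
                    ]
                )
                roi_i = np.stack(
                    [
                        resize_bilinear(crop[..., ch], self.inc_roi, self.inc_roi)
                        for ch in range(3)
                    ]
                )
                examples.append(
                    {
                        "roi_m": roi_m.astype(np.float32),
                        "roi_i": roi_i.astype(np.float32),
                        "mpc": triple.mpc,
                        "mpi": mpi,
                        "minc_oi": minc_oi,
                    }
                )
        return examples

    # -- training -------------------------------------------------------

    def fit(self, X, y=None) -> "DualDecoderHead":
        """Train on a sequence of fixture scenes (with ``rgb`` rendered)."""
        cfg = self._config()
        rng = np.random.default_rng(self.seed)
        self.net_ = _HeadNet(cfg, rng)
        self.encoder_ = _RoiEncoder(cfg.channels, rng)
        examples = self._examples_from_scenes(X, rng)
        if not examples:
            raise ValueError("no usable proposals found in the scenes")
        params = self.net_.parameters() + self.encoder_.parameters()
        opt = Adam(params, lr=self.lr)
        self.loss_history_ = []
        for it in range(self.n_iters):
            idx = rng.choice(len(examples), size=min(self.batch_size, len(examples)))
            batch = [examples[i] for i in idx]
            f_m = self.encoder_(Tensor(np.stack([b["roi_m"] for b in batch])))
            f_i = self.encoder_(Tensor(np.stack([b["roi_i"] for b in batch])))
            p_m, p_i = self.net_(f_m, f_i)
            mpc = np.stack([b["mpc"] for b in batch])[:, None].astype(float)
            mpi = np.stack([b["mpi"] for b in batch])[:, None].astype(float)
            minc = np.stack([b["minc_oi"] for b in batch])[:, None].astype(float)
            loss = mask_loss(p_m, mpc) + incoherent_loss(
                p_i, mpi, minc, self.lambda_inc
            )
            opt.zero_grad()
            loss.backward()
            lr = (
                warmup_cosine_lr(self.lr, it, self.n_iters)
                if self.lr_schedule
                else self.lr
            )
            opt.step(lr=lr)
            self.loss_history_.append(float(loss.data))
        return self

    def forward(self, f_m_roi, f_i_roi) -> HeadPrediction:
        """Run the decoders on ROI feature grids (N,c,14,14) / (N,c,28,28)."""
        if not hasattr(self, "net_"):
            # Allow structural use without training.
            rng = np.random.default_rng(self.seed)
            self.net_ = _HeadNet(self._config(), rng)
        f_m = f_m_roi if isinstance(f_m_roi, Tensor) else Tensor(f_m_roi)
        f_i = f_i_roi if isinstance(f_i_roi, Tensor) else Tensor(f_i_roi)
        cfg = self._config()
        if f_m.shape[2:] != (cfg.mask_roi, cfg.mask_roi):
            raise ValueError(f"mask ROI must be {cfg.mask_roi}px, got {f_m.shape}")
        if f_i.shape[2:] != (cfg.inc_roi, cfg.inc_roi):
            raise ValueError(f"inc ROI must be {cfg.inc_roi}px, got {f_i.shape}")
        if f_m.shape[1] != cfg.channels or f_i.shape[1] != cfg.channels:
            raise ValueError("channel count does not match config")
        t_m, t_i = self.net_(f_m, f_i)
        return HeadPrediction(
            p_m=t_m.data[:, 0], p_i=t_i.data[:, 0], t_m=t_m, t_i=t_i
        )
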