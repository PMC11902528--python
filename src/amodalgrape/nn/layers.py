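"""Convnet layers, losses, and the Adam optimizer."""

from __future__ import annotations

import numpy as np

from amodalgrape.nn.autodiff import Tensor, concat, conv2d, conv_transpose2d

__all__ = [
    "Module",
    "Sequential",
    "Conv2d",
    "ConvTranspose2d",
    "SE",
    "Adam",
    "bce_loss",
    "dice_loss",
]

_EPS = 1e-7

# Network parameters are kept in single precision for speed; graphs built
# from float64 inputs (e.g. the public loss functions) stay in double.
PARAM_DTYPE = np.float32


class Module:
    """Minimal layer base: parameter collection and state dict round trip."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(arrays):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.asarray(a, dtype=p.data.dtype).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    w = rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)
    return Tensor(w.astype(PARAM_DTYPE), requires_grad=True)


class Conv2d(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int = 3,
        stride: int = 1,
        pad: int | None = None,
        relu: bool = True,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        self.use_relu = relu
        self.w = _he_init(rng, (c_out, c_in, k, k), c_in * k * k)
        self.b = Tensor(np.zeros(c_out, dtype=PARAM_DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        y = conv2d(x, self.w, self.b, self.stride, self.pad)
        return y.relu() if self.use_relu else y


class ConvTranspose2d(Module):
    """2x learned upsampling (kernel 2, stride 2 by default)."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int = 2,
        stride: int = 2,
        relu: bool = True,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.use_relu = relu
        self.w = _he_init(rng, (c_in, c_out, k, k), c_in * k * k)
        self.b = Tensor(np.zeros(c_out, dtype=PARAM_DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        y = conv_transpose2d(x, self.w, self.b, self.stride)
        return y.relu() if self.use_relu else y


class SE(Module):
    """Squeeze-and-excitation channel attention (reduction ratio 4)."""

    def __init__(self, c: int, reduction: int = 4, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        c_mid = max(1, c // reduction)
        self.fc1 = Conv2d(c, c_mid, k=1, pad=0, relu=True, rng=rng)
        self.fc2 = Conv2d(c_mid, c, k=1, pad=0, relu=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        s = x.mean(axis=(2, 3), keepdims=True)
        s = self.fc2(self.fc1(s)).sigmoid()
        return x * s


def bce_loss(p: Tensor, target: np.ndarray, weight: np.ndarray | None = None) -> Tensor:
    """Mean binary cross-entropy on probabilities, clamped to [1e-7, 1-1e-7].

    ``weight`` restricts the loss to a region: both prediction and target
    are multiplied by it elementwise before the BCE (the mean stays over
    all pixels, so region size acts as an implicit weight).
    """
    t = np.asarray(target, dtype=p.data.dtype)
    if weight is not None:
        wm = np.asarray(weight, dtype=p.data.dtype)
        p = p * Tensor(wm)
        t = t * wm
    pc = p.clip(_EPS, 1.0 - _EPS)
    tt = Tensor(t)
    loss = -(tt * pc.log() + (1.0 - tt) * (1.0 - pc).log())
    return loss.mean()


def dice_loss(p: Tensor, target: np.ndarray) -> Tensor:
    """Soft dice loss with +1 smoothing: 1 - (2*sum(p*t)+1)/(sum(p^2)+sum(t^2)+1)."""
    t = Tensor(np.asarray(target, dtype=p.data.dtype))
    num = 2.0 * (p * t).sum() + 1.0
    den = p.square().sum() + t.square().sum() + 1.0
    return 1.0 - num / den


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - lr * m_hat / (np.sqrt(v_hat) + self.eps)


def warmup_cosine_lr(base_lr: float, step: int, total: int, warmup: int = 50) -> float:
    """Linear warm-up followed by cosine annealing to 1% of base."""
    if step < warmup:
        return base_lr * (step + 1) / warmup
    frac = (step - warmup) / max(1, total - warmup)
    return base_lr * (0.01 + 0.99 * 0.5 * (1 + np.cos(np.pi * frac)))
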