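"""Minimal numpy building blocks for small convolutional networks.

Forward passes are float32 and deterministic.  Each layer caches what its
backward pass needs only when called with ``train=True``; inference never
allocates caches.  Convolutions are stride-1 'same' convolutions implemented
with ``sliding_window_view`` + ``einsum``, which is fast enough for the
desk-scale networks used here (32x32 inputs, tens of filters).
"""

from __future__ import annotations

import numpy as np


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C, H, W, kh, kw) patch view with 'same' zero padding."""
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    return np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))


class Conv2d:
    """Stride-1 'same' convolution with He-initialized weights."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, rng: np.random.Generator):
        k = kernel_size
        std = np.sqrt(2.0 / (in_channels * k * k))
        self.w = rng.normal(0.0, std, size=(out_channels, in_channels, k, k)).astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    @property
    def out_channels(self) -> int:
        return self.w.shape[0]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        patches = _im2col(x, self.w.shape[2], self.w.shape[3])
        out = np.einsum("nchwij,kcij->nkhw", patches, self.w, optimize=True)
        out += self.b[None, :, None, None]
        if train:
            self._cache = patches
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        patches = self._cache
        self.gw += np.einsum("nchwij,nkhw->kcij", patches, gout, optimize=True)
        self.gb += gout.sum(axis=(0, 2, 3))
        w_flip = self.w[:, :, ::-1, ::-1]
        gpatches = _im2col(gout, self.w.shape[2], self.w.shape[3])
        return np.einsum("nkhwij,kcij->nchw", gpatches, w_flip, optimize=True)

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class GainReLU:
    """Rectifier with a per-filter gain: out_k = (1 + alpha_k) * max(0, pre_k).

    ``alpha = 0`` is the conventional ReLU, ``alpha = -1`` silences the filter
    (lesion), ``alpha > 0`` raises its gain (feature-based attention).
    """

    def __init__(self, n_channels: int):
        self.alpha = np.zeros(n_channels, dtype=np.float32)
        self._cache = None

    def forward(self, pre: np.ndarray, train: bool = False) -> np.ndarray:
        mask = pre > 0
        out = np.where(mask, pre, 0.0).astype(np.float32)
        out *= (1.0 + self.alpha)[None, :, None, None]
        if train:
            self._cache = mask
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._cache * (1.0 + self.alpha)[None, :, None, None]

    def params(self):
        return []


class MaxPool2:
    """2x2 max pooling, stride 2. Input H, W must be even."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        view = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = view.max(axis=(3, 5))
        if train:
            self._cache = (view, out, x.shape)
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        view, out, shape = self._cache
        mask = view == out[:, :, :, None, :, None]
        g = mask * gout[:, :, :, None, :, None]
        return g.reshape(shape).astype(np.float32)

    def params(self):
        return []


class Flatten:
    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout.reshape(self._shape)

    def params(self):
        return []


class Linear:
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / in_features)
        self.w = rng.normal(0.0, std, size=(out_features, in_features)).astype(np.float32)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._cache = x
        return x @ self.w.T + self.b

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x = self._cache
        self.gw += gout.T @ x
        self.gb += gout.sum(axis=0)
        return (gout @ self.w).astype(np.float32)

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class ReLU:
    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        mask = x > 0
        if train:
            self._cache = mask
        return np.where(mask, x, 0.0).astype(np.float32)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._cache

    def params(self):
        return []


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(
    logits: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean (weighted) cross-entropy loss and its gradient w.r.t. the logits."""
    n = len(y)
    p = softmax(logits)
    if sample_weight is None:
        sample_weight = np.ones(n)
    wsum = sample_weight.sum()
    logp = np.log(np.clip(p[np.arange(n), y], 1e-12, None))
    loss = float(-(sample_weight * logp).sum() / wsum)
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    grad *= (sample_weight / wsum)[:, None]
    return loss, grad.astype(np.float32)


class SGD:
    """Plain SGD with optional momentum over a list of layers."""

    def __init__(self, layers, lr: float, momentum: float = 0.0,
                 clip_norm: float | None = None):
        self.pairs = [pg for layer in layers for pg in layer.params()]
        self.lr = lr
        self.momentum = momentum
        self.clip_norm = clip_norm
        self.vel = [np.zeros_like(p) for p, _ in self.pairs]

    def zero_grad(self) -> None:
        for _, g in self.pairs:
            g[...] = 0.0

    def step(self) -> None:
        if self.clip_norm is not None:
            total = np.sqrt(sum(float(np.sum(g**2)) for _, g in self.pairs))
            if total > self.clip_norm:
                scale = self.clip_norm / total
                for _, g in self.pairs:
                    g *= scale
        for v, (p, g) in zip(self.vel, self.pairs):
            v *= self.momentum
            v -= self.lr * g
            p += v
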