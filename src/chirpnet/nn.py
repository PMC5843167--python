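"""Minimal numpy CNN: valid convolutions, 2x2 max-pooling, dense layers.

The window classifier is small (two or three conv/pool blocks and one dense
layer on a 130x20 input), so a direct numpy implementation with
``sliding_window_view``-based convolutions is fast enough for training on a
single CPU and keeps the package dependency-light.  Convolutions are
*valid* (no padding): unpadded evaluation is what makes the sliding-window
and fully-convolutional paths agree exactly (see ``models.predict_fullconv``).

Shapes follow the (N, C, H, W) convention.  All randomness flows through a
seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "MaxPool2",
    "ReLU",
    "Dense",
    "SoftmaxCrossEntropy",
    "Adam",
    "conv_valid",
]


def conv_valid(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """Valid cross-correlation of a batch ``x (N,C,H,W)`` with ``w (F,C,kh,kw)``."""
    kh, kw = w.shape[2], w.shape[3]
    patches = sliding_window_view(x, (kh, kw), axis=(2, 3))  # (N,C,H',W',kh,kw)
    out = np.tensordot(patches, w, axes=([1, 4, 5], [1, 2, 3]))  # (N,H',W',F)
    out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
    if b is not None:
        out += b[None, :, None, None]
    return out


class Conv2D:
    """Valid 2-D convolution layer with He-initialised weights.

    Forward runs as im2col + one BLAS matmul; the column matrix is cached
    in training mode so the weight gradient is a second matmul and the
    input gradient a cheap shifted-slice accumulation.  ``first=True``
    skips the input gradient (nothing below needs it).  float32 throughout.
    """

    def __init__(self, in_ch: int, out_ch: int, kh: int, kw: int,
                 rng: np.random.Generator, first: bool = False):
        fan_in = in_ch * kh * kw
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kh, kw)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.first = first
        self._cache = None

    @property
    def params(self):
        return [self.w, self.b]

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        kh, kw = self.w.shape[2], self.w.shape[3]
        oh, ow = h - kh + 1, w - kw + 1
        if oh < 1 or ow < 1:
            raise ValueError(
                f"conv kernel {kh}x{kw} collapses a {h}x{w} input below size 1"
            )
        return oh, ow

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        f, c, kh, kw = self.w.shape
        n = x.shape[0]
        oh, ow = self.out_shape(x.shape[2], x.shape[3])
        patches = sliding_window_view(x, (kh, kw), axis=(2, 3))  # (N,C,oh,ow,kh,kw)
        xcol = np.ascontiguousarray(patches.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * oh * ow, c * kh * kw
        )
        out = xcol @ self.w.reshape(f, -1).T + self.b
        if train:
            self._cache = (xcol, x.shape, (oh, ow))
        return np.ascontiguousarray(
            out.reshape(n, oh, ow, f).transpose(0, 3, 1, 2)
        )

    def backward(self, dout: np.ndarray):
        xcol, x_shape, (oh, ow) = self._cache
        f, c, kh, kw = self.w.shape
        n = x_shape[0]
        dout_mat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, f)
        dw = (dout_mat.T @ xcol).reshape(f, c, kh, kw)
        db = dout_mat.sum(axis=0)
        if self.first:
            return None, [dw, db]
        dcol = (dout_mat @ self.w.reshape(f, -1)).reshape(n, oh, ow, c, kh, kw)
        dcol = np.ascontiguousarray(dcol.transpose(0, 3, 1, 2, 4, 5))
        dx = np.zeros(x_shape, dtype=dout.dtype)
        for i in range(kh):
            for j in range(kw):
                dx[:, :, i : i + oh, j : j + ow] += dcol[:, :, :, :, i, j]
        return dx, [dw, db]


class MaxPool2:
    """2x2 max-pooling with stride 2; odd trailing rows/columns dropped."""

    params: list = []

    def __init__(self):
        self._cache = None

    @staticmethod
    def out_shape(h: int, w: int) -> tuple[int, int]:
        if h < 2 or w < 2:
            raise ValueError(f"cannot 2x2-pool a {h}x{w} feature map")
        return h // 2, w // 2

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :, : 2 * h2, : 2 * w2]
        blocks = xc.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = blocks.reshape(n, c, h2, w2, 4)
        idx = flat.argmax(axis=4)
        out = np.take_along_axis(flat, idx[..., None], axis=4)[..., 0]
        if train:
            self._cache = (x.shape, idx)
        return out

    def backward(self, dout: np.ndarray):
        (n, c, h, w), idx = self._cache
        h2, w2 = h // 2, w // 2
        dflat = np.zeros((n, c, h2, w2, 4), dtype=dout.dtype)
        np.put_along_axis(dflat, idx[..., None], dout[..., None], axis=4)
        dx = np.zeros((n, c, h, w), dtype=dout.dtype)
        dx[:, :, : 2 * h2, : 2 * w2] = (
            dflat.reshape(n, c, h2, w2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, 2 * h2, 2 * w2)
        )
        return dx, []


class ReLU:
    params: list = []

    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray):
        return dout * self._mask, []


class Dense:
    """Fully connected layer on flattened (N, D) inputs."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self._x = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray):
        dw = self._x.T @ dout
        db = dout.sum(axis=0)
        dx = dout @ self.w.T
        return dx, [dw, db]


class SoftmaxCrossEntropy:
    """Combined softmax + cross-entropy head for integer labels."""

    @staticmethod
    def probs(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    @classmethod
    def loss_and_grad(cls, logits: np.ndarray, y: np.ndarray):
        p = cls.probs(logits)
        n = logits.shape[0]
        eps = 1e-12
        loss = -np.log(p[np.arange(n), y] + eps).mean()
        dlogits = p.copy()
        dlogits[np.arange(n), y] -= 1.0
        return loss, dlogits / n


class Adam:
    """Adam optimiser over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
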