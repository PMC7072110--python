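"""Minimal NumPy building blocks for small convolutional segmentation nets.

Vectorized im2col convolutions, 2x2 max pooling, nearest-neighbor
upsampling and an Adam optimizer — enough to train desk-scale encoder–
decoder networks deterministically on a CPU. Arrays are NCHW float32;
every layer caches what its backward pass needs, so a layer instance
supports one forward/backward pair at a time.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Conv2D:
    """Same-padded 2-D convolution. Weights He-initialized from ``rng``."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        scale = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.W = (rng.standard_normal((c_out, c_in * kernel * kernel)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (N, C, H, W, k, k) -> (N*H*W, C*k*k)
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * k * k)
        out = cols @ self.W.T + self.b
        if cache:
            self._cols = cols
            self._xshape = x.shape
        return np.ascontiguousarray(out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._cols is None or self._xshape is None:
            raise RuntimeError("backward called before forward")
        n, c, h, w = self._xshape
        k = self.k
        p = k // 2
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(n * h * w, self.c_out)
        self.dW = (dmat.T @ self._cols).astype(np.float32)
        self.db = dmat.sum(axis=0).astype(np.float32)
        dcols = (dmat @ self.W).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di : di + h, dj : dj + w] += dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p : p + h, p : p + w] if p else dxp

    def params(self):
        return [("W", self), ("b", self)]


class MaxPool2:
    """2x2 max pooling with stride 2 (spatial dims must be even)."""

    def __init__(self):
        self._idx: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial dims must be even for 2x2 pooling")
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4
        )
        idx = blocks.argmax(axis=-1)
        out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
        if cache:
            self._idx = idx
            self._shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dblocks = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dblocks, self._idx[..., None], dout[..., None], axis=-1)
        dx = dblocks.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        self._idx = None
        return dx


def upsample2(x: np.ndarray) -> np.ndarray:
    """Nearest-neighbor 2x upsampling."""
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def upsample2_backward(dout: np.ndarray) -> np.ndarray:
    n, c, h, w = dout.shape
    return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        if cache:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Adam:
    """Adaptive-moment gradient descent over a list of Conv2D layers."""

    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = list(layers)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [(np.zeros_like(l.W), np.zeros_like(l.b)) for l in self.layers]
        self._v = [(np.zeros_like(l.W), np.zeros_like(l.b)) for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for layer, m, v in zip(self.layers, self._m, self._v):
            for param, grad, mm, vv in (
                (layer.W, layer.dW, m[0], v[0]),
                (layer.b, layer.db, m[1], v[1]),
            ):
                mm *= self.beta1
                mm += (1.0 - self.beta1) * grad
                vv *= self.beta2
                vv += (1.0 - self.beta2) * grad * grad
                param -= self.lr * (mm / b1t) / (np.sqrt(vv / b2t) + self.eps)
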