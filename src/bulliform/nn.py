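"""Minimal deterministic CPU neural-network primitives (NHWC, float32).

Just enough machinery for a small U-net: 3x3 same-padding convolution
(im2col), 2x2 max-pooling, non-overlapping 2x2 transposed convolution,
ReLU, numerically stable binary cross-entropy on logits, and Adam.
Everything is plain numpy, so results are exactly reproducible for a
given seed on any backend.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


def he_init(shape, fan_in, rng) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N,H,W,C) -> (N,H,W,9C) patches for 3x3 same-padding convolution."""
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (N,H,W,C,3,3)
    win = win.transpose(0, 1, 2, 4, 5, 3)  # (N,H,W,3,3,C)
    n, h, w = x.shape[:3]
    return np.ascontiguousarray(win).reshape(n, h, w, -1)


class Conv3x3:
    """3x3 convolution, stride 1, same padding, optional ReLU."""

    def __init__(self, c_in: int, c_out: int, rng, relu: bool = True):
        self.W = he_init((3, 3, c_in, c_out), 9 * c_in, rng)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.relu = relu
        self.c_in, self.c_out = c_in, c_out

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols = _im2col3(x)
        z = cols @ self.W.reshape(-1, self.c_out) + self.b
        self._cols, self._z = cols, z if self.relu else None
        if self.relu:
            return np.maximum(z, 0.0)
        return z

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.relu:
            dout = dout * (self._z > 0)
        n, h, w, _ = dout.shape
        dflat = dout.reshape(-1, self.c_out)
        self.dW = (self._cols.reshape(-1, 9 * self.c_in).T @ dflat).reshape(self.W.shape)
        self.db = dflat.sum(axis=0)
        # dx = "full" correlation of dout with the flipped kernel
        w_flip = self.W[::-1, ::-1].transpose(0, 1, 3, 2)  # (3,3,c_out,c_in)
        cols_d = _im2col3(dout)
        dx = cols_d @ w_flip.reshape(-1, self.c_in)
        self._cols = self._z = None
        return dx

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class MaxPool2:
    """2x2 max pooling, stride 2. Gradient is split evenly among ties."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        self._x_r, self._out = xr, out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mask = self._x_r == self._out[:, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4), keepdims=True)
        dx = mask * (dout[:, :, None, :, None, :] / counts)
        n, hh, _, ww, _, c = dx.shape
        self._x_r = self._out = None
        return dx.reshape(n, hh * 2, ww * 2, c)

    def params(self):
        return {}

    def grads(self):
        return {}


class UpConv2x2:
    """Transposed convolution, kernel 2x2, stride 2 (non-overlapping)."""

    def __init__(self, c_in: int, c_out: int, rng):
        self.W = he_init((c_in, c_out, 2, 2), c_in, rng)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.c_in, self.c_out = c_in, c_out

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, h, w, _ = x.shape
        t = np.tensordot(x, self.W, axes=([3], [0]))  # (N,H,W,c_out,2,2)
        t = t.transpose(0, 1, 4, 2, 5, 3)  # (N,H,2,W,2,c_out)
        return t.reshape(n, 2 * h, 2 * w, self.c_out) + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h2, w2, _ = dout.shape
        d = dout.reshape(n, h2 // 2, 2, w2 // 2, 2, self.c_out)
        d = d.transpose(0, 1, 3, 5, 2, 4)  # (N,H,W,c_out,2,2)
        self.dW = np.einsum("nhwc,nhwfij->cfij", self._x, d).astype(DTYPE)
        self.db = dout.sum(axis=(0, 1, 2))
        dx = np.tensordot(d, self.W, axes=([3, 4, 5], [1, 2, 3]))
        self._x = None
        return dx.astype(DTYPE)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray):
    """Mean pixel-wise binary cross-entropy and its gradient wrt logits."""
    z = z.astype(np.float64)
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    dz = ((sigmoid(z) - y) / z.size).astype(DTYPE)
    return float(loss), dz


class Adam:
    """Adaptive-moment estimation over a flat {name: array} parameter dict."""

    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
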