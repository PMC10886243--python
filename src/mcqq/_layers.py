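"""Minimal 3-D convolutional layer framework with reverse-mode gradients.

Implements exactly the pieces the dual-U-Net needs — 3-D convolution
(zero-padded), 2x2x2 max pooling, 2x2x2 transposed convolution, ReLU, skip
concatenation — plus the Adam optimizer.  Single-volume (no batch axis)
tensors of shape (channels, x, y, z), float64 throughout so training runs
are bit-reproducible across repeats on the same machine.

Each layer caches what its backward pass needs; ``backward`` consumes the
upstream gradient and returns the gradient with respect to the layer input,
accumulating parameter gradients in ``layer.grads``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv3d", "MaxPool3d", "Deconv3d", "ReLU", "Adam", "Layer"]


class Layer:
    """Base class; parameter-free layers leave ``params`` empty."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


def _he_init(rng, shape, fan_in):
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Conv3d(Layer):
    """3-D convolution, kernel k (1 or 3), stride 1, zero padding (k-1)//2."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng):
        super().__init__()
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan_in = c_in * kernel ** 3
        self.params = {
            "W": _he_init(rng, (c_out, c_in, kernel, kernel, kernel), fan_in),
            "b": np.zeros(c_out),
        }
        self.zero_grad()

    def forward(self, x):
        self._xshape = x.shape
        k, p = self.k, (self.k - 1) // 2
        if p:
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
        else:
            xp = x
        # cols: (X, Y, Z, c_in*k^3)
        win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
        cols = win.transpose(1, 2, 3, 0, 4, 5, 6).reshape(*x.shape[1:], -1)
        self._cols = cols
        W2 = self.params["W"].reshape(self.c_out, -1)
        out = cols @ W2.T + self.params["b"]
        return np.ascontiguousarray(out.transpose(3, 0, 1, 2))

    def backward(self, gy):
        k, p = self.k, (self.k - 1) // 2
        g2 = gy.transpose(1, 2, 3, 0).reshape(-1, self.c_out)  # (XYZ, c_out)
        cols2 = self._cols.reshape(-1, self._cols.shape[-1])
        self.grads["W"] += (g2.T @ cols2).reshape(self.params["W"].shape)
        self.grads["b"] += g2.sum(axis=0)
        # input gradient: full correlation of gy with flipped kernels
        gcols = g2 @ self.params["W"].reshape(self.c_out, -1)  # (XYZ, c_in*k^3)
        gcols = gcols.reshape(*gy.shape[1:], self.c_in, k, k, k)
        gx = np.zeros((self.c_in,) + tuple(s + 2 * p for s in gy.shape[1:]))
        X, Y, Z = gy.shape[1:]
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    gx[:, i:i + X, j:j + Y, l:l + Z] += np.moveaxis(
                        gcols[..., i, j, l], -1, 0)
        if p:
            gx = gx[:, p:-p, p:-p, p:-p]
        return gx


class MaxPool3d(Layer):
    """2x2x2 max pooling; spatial dims must be even."""

    def forward(self, x):
        c, X, Y, Z = x.shape
        if X % 2 or Y % 2 or Z % 2:
            raise ValueError("max pooling requires even spatial dimensions")
        r = x.reshape(c, X // 2, 2, Y // 2, 2, Z // 2, 2)
        r = r.transpose(0, 1, 3, 5, 2, 4, 6).reshape(c, X // 2, Y // 2, Z // 2, 8)
        self._argmax = r.argmax(axis=-1)
        self._xshape = x.shape
        return r.max(axis=-1)

    def backward(self, gy):
        c, X, Y, Z = self._xshape
        flat = np.zeros((c, X // 2, Y // 2, Z // 2, 8))
        np.put_along_axis(flat, self._argmax[..., None], gy[..., None], axis=-1)
        flat = flat.reshape(c, X // 2, Y // 2, Z // 2, 2, 2, 2)
        return flat.transpose(0, 1, 4, 2, 5, 3, 6).reshape(c, X, Y, Z)


class Deconv3d(Layer):
    """Transposed convolution with 2x2x2 kernel, stride 2 (upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.params = {
            "W": _he_init(rng, (c_in, c_out, 2, 2, 2), c_in),
            "b": np.zeros(c_out),
        }
        self.zero_grad()

    def forward(self, x):
        self._x = x
        W = self.params["W"]
        # out[o, 2x+i, 2y+j, 2z+l] = sum_c W[c,o,i,j,l] x[c,x,y,z] + b[o]
        t = np.einsum("cxyz,coijl->oxiyjzl", x, W)
        c_out = self.c_out
        X, Y, Z = x.shape[1:]
        out = t.reshape(c_out, 2 * X, 2 * Y, 2 * Z) + self.params["b"][:, None, None, None]
        return out

    def backward(self, gy):
        x = self._x
        X, Y, Z = x.shape[1:]
        g = gy.reshape(self.c_out, X, 2, Y, 2, Z, 2).transpose(0, 1, 3, 5, 2, 4, 6)
        # g: (c_out, X, Y, Z, 2, 2, 2)
        self.grads["W"] += np.einsum("cxyz,oxyzijl->coijl", x, g)
        self.grads["b"] += gy.sum(axis=(1, 2, 3))
        gx = np.einsum("oxyzijl,coijl->cxyz", g, self.params["W"])
        return gx


class ReLU(Layer):
    def forward(self, x):
        self._pos = x > 0
        return np.where(self._pos, x, 0.0)

    def backward(self, gy):
        return np.where(self._pos, gy, 0.0)


class Adam:
    """Adam optimizer over a list of layers' parameter dicts."""

    def __init__(self, layers, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = [ly for ly in layers if ly.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in ly.params.items()} for ly in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in ly.params.items()} for ly in self.layers]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for ly, m, v in zip(self.layers, self.m, self.v):
            for k, p in ly.params.items():
                g = ly.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)

    def zero_grad(self):
        for ly in self.layers:
            ly.zero_grad()
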