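"""Minimal NumPy layer stack with explicit backprop.

Only what the architecture needs: valid 1-D convolution, padded 2-D
convolution, non-overlapping max pooling, dense layers, ReLU, inverted
dropout and a flatten.  Convolutions run as im2col + GEMM in float32; the
col2im pass loops over the (small) kernel taps with vectorized adds.

Every layer exposes ``forward(x, train=False)``, ``backward(grad)`` and
``params()`` returning ``[(name, weight, grad), ...]`` views that an
optimizer updates in place.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer", "Conv1D", "Conv2D", "MaxPool1D", "MaxPool2D",
    "Dense", "ReLU", "Dropout", "Flatten", "Sequential",
    "conv_out_len",
]


def conv_out_len(length: int, kernel: int, stride: int = 1, pad: int = 0) -> int:
    """floor((L - k + 2p)/s) + 1 — the standard conv/pool output-size rule."""
    return (length - kernel + 2 * pad) // stride + 1


def he_init(rng: np.random.Generator, shape: Tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Layer:
    def params(self) -> List[Tuple[str, np.ndarray, np.ndarray]]:
        return []

    def forward(self, x, train: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Conv1D(Layer):
    """Valid (pad 0, stride 1, dilation 1) 1-D convolution over (B, C, L)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.W = he_init(rng, (c_in * kernel, c_out), c_in * kernel)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def forward(self, x, train: bool = False):
        B, C, L = x.shape
        if L < self.kernel:
            raise ValueError(f"input length {L} shorter than kernel {self.kernel}")
        l_out = L - self.kernel + 1
        # (B, C, l_out, K) -> (B, l_out, C, K) -> (B*l_out, C*K)
        cols = sliding_window_view(x, self.kernel, axis=2)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(B * l_out, -1)
        self._cols, self._in_shape = cols, x.shape
        y = cols @ self.W + self.b
        return y.reshape(B, l_out, self.c_out).transpose(0, 2, 1)

    def backward(self, grad):
        B, C, L = self._in_shape
        l_out = L - self.kernel + 1
        g = np.ascontiguousarray(grad.transpose(0, 2, 1)).reshape(B * l_out, self.c_out)
        self.dW[...] = self._cols.T @ g
        self.db[...] = g.sum(axis=0)
        dcols = (g @ self.W.T).reshape(B, l_out, C, self.kernel)
        dx = np.zeros((B, C, L), dtype=grad.dtype)
        for k in range(self.kernel):
            dx[:, :, k:k + l_out] += dcols[:, :, :, k].transpose(0, 2, 1)
        return dx


class Conv2D(Layer):
    """Stride-1 2-D convolution with symmetric zero padding over (B, C, H, W)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, pad: int,
                 rng: np.random.Generator):
        self.c_in, self.c_out, self.kernel, self.pad = c_in, c_out, kernel, pad
        self.W = he_init(rng, (c_in * kernel * kernel, c_out), c_in * kernel * kernel)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def forward(self, x, train: bool = False):
        p, k = self.pad, self.kernel
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        B, C, H, W = xp.shape
        h_out, w_out = H - k + 1, W - k + 1
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))  # (B,C,h,w,k,k)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5))
        cols = cols.reshape(B * h_out * w_out, C * k * k)
        self._cols, self._pad_shape, self._in_shape = cols, xp.shape, x.shape
        y = cols @ self.W + self.b
        return y.reshape(B, h_out, w_out, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad):
        p, k = self.pad, self.kernel
        B, C, H, W = self._pad_shape
        h_out, w_out = H - k + 1, W - k + 1
        g = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(-1, self.c_out)
        self.dW[...] = self._cols.T @ g
        self.db[...] = g.sum(axis=0)
        dcols = (g @ self.W.T).reshape(B, h_out, w_out, C, k, k)
        dxp = np.zeros((B, C, H, W), dtype=grad.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + h_out, j:j + w_out] += \
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if p:
            return dxp[:, :, p:H - p, p:W - p]
        return dxp


class MaxPool1D(Layer):
    """Non-overlapping max pooling (kernel == stride); tail positions that do
    not fill a window are dropped, matching floor((L-k)/s)+1."""

    def __init__(self, kernel: int):
        self.kernel = kernel

    def forward(self, x, train: bool = False):
        B, C, L = x.shape
        k = self.kernel
        l_out = (L - k) // k + 1
        xt = x[:, :, :l_out * k].reshape(B, C, l_out, k)
        self._arg = xt.argmax(axis=3)
        self._in_shape = x.shape
        return xt.max(axis=3)

    def backward(self, grad):
        B, C, L = self._in_shape
        k = self.kernel
        l_out = grad.shape[2]
        dxt = np.zeros((B, C, l_out, k), dtype=grad.dtype)
        np.put_along_axis(dxt, self._arg[..., None], grad[..., None], axis=3)
        dx = np.zeros((B, C, L), dtype=grad.dtype)
        dx[:, :, :l_out * k] = dxt.reshape(B, C, l_out * k)
        return dx


class MaxPool2D(Layer):
    """Non-overlapping 2-D max pooling with kernel (kh, kw) == stride."""

    def __init__(self, kh: int, kw: int):
        self.kh, self.kw = kh, kw

    def forward(self, x, train: bool = False):
        B, C, H, W = x.shape
        kh, kw = self.kh, self.kw
        h_out, w_out = (H - kh) // kh + 1, (W - kw) // kw + 1
        xt = x[:, :, :h_out * kh, :w_out * kw]
        xt = xt.reshape(B, C, h_out, kh, w_out, kw).transpose(0, 1, 2, 4, 3, 5)
        flat = xt.reshape(B, C, h_out, w_out, kh * kw)
        self._arg = flat.argmax(axis=4)
        self._in_shape = x.shape
        return flat.max(axis=4)

    def backward(self, grad):
        B, C, H, W = self._in_shape
        kh, kw = self.kh, self.kw
        h_out, w_out = grad.shape[2], grad.shape[3]
        dflat = np.zeros((B, C, h_out, w_out, kh * kw), dtype=grad.dtype)
        np.put_along_axis(dflat, self._arg[..., None], grad[..., None], axis=4)
        dxt = dflat.reshape(B, C, h_out, w_out, kh, kw).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros((B, C, H, W), dtype=grad.dtype)
        dx[:, :, :h_out * kh, :w_out * kw] = dxt.reshape(B, C, h_out * kh, w_out * kw)
        return dx


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = he_init(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def forward(self, x, train: bool = False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T


class ReLU(Layer):
    def forward(self, x, train: bool = False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in eval mode.  The RNG is supplied by the
    training loop so one seed controls every stochastic element."""

    def __init__(self, rate: float, rng: Optional[np.random.Generator] = None):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train: bool = False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, train: bool = False):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Sequential(Layer):
    def __init__(self, layers: List[Layer]):
        self.layers = layers

    def params(self):
        out = []
        for i, layer in enumerate(self.layers):
            for name, w, g in layer.params():
                out.append((f"{i}.{name}", w, g))
        return out

    def forward(self, x, train: bool = False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad
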