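"""Neural-network layers in NumPy with explicit forward/backward passes.

All tensors are float32 in NCHW layout (module-global ``DTYPE``;
tests flip it to float64 for finite-difference gradient verification).  Each layer caches what its
backward pass needs; ``params()`` exposes (value, gradient) pairs for
the optimizer.  Convolutions are expressed as a sum over kernel offsets
of channel-mixing tensordots, which keeps both directions vectorised
without materialising im2col buffers.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32

__all__ = [
    "BatchNorm2d",
    "Conv2d",
    "ConvTranspose2d",
    "Layer",
    "MaxPool2d",
    "ReLU",
]


class Layer:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 (or any odd k) same-padding convolution, stride 1."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, rng=None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel * kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            (c_out, c_in, kernel, kernel)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.kernel = kernel
        self.pad = kernel // 2

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=True):
        p = self.pad
        self._xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        n, _, h, w = x.shape
        out = np.zeros((n, h, w, self.W.shape[0]), dtype=self.W.dtype)
        for di in range(self.kernel):
            for dj in range(self.kernel):
                patch = self._xp[:, :, di:di + h, dj:dj + w]
                out += np.tensordot(patch, self.W[:, :, di, dj], axes=([1], [1]))
        self._shape = x.shape
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2)) + self.b[None, :, None, None]

    def backward(self, grad):
        n, _, h, w = self._shape
        self.db[:] = grad.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(self._xp)
        for di in range(self.kernel):
            for dj in range(self.kernel):
                patch = self._xp[:, :, di:di + h, dj:dj + w]
                self.dW[:, :, di, dj] = np.tensordot(grad, patch, axes=([0, 2, 3], [0, 2, 3]))
                dxp[:, :, di:di + h, dj:dj + w] += np.tensordot(
                    grad, self.W[:, :, di, dj], axes=([1], [0])
                ).transpose(0, 3, 1, 2)
        p = self.pad
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class ConvTranspose2d(Layer):
    """2x2 stride-2 transposed convolution: exact 2x learnable upsampling."""

    def __init__(self, c_in: int, c_out: int, rng=None):
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, np.sqrt(2.0 / c_in), (c_in, c_out, 2, 2)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=True):
        self._x = x
        n, _, h, w = x.shape
        c_out = self.W.shape[1]
        out = np.empty((n, c_out, 2 * h, 2 * w), dtype=self.W.dtype)
        for di in range(2):
            for dj in range(2):
                out[:, :, di::2, dj::2] = np.tensordot(
                    x, self.W[:, :, di, dj], axes=([1], [0])
                ).transpose(0, 3, 1, 2)
        return out + self.b[None, :, None, None]

    def backward(self, grad):
        self.db[:] = grad.sum(axis=(0, 2, 3))
        dx = np.zeros_like(self._x)
        for di in range(2):
            for dj in range(2):
                g = grad[:, :, di::2, dj::2]
                self.dW[:, :, di, dj] = np.tensordot(self._x, g, axes=([0, 2, 3], [0, 2, 3]))
                dx += np.tensordot(g, self.W[:, :, di, dj], axes=([1], [1])).transpose(0, 3, 1, 2)
        return dx


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=DTYPE)
        self.beta = np.zeros(c, dtype=DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) * self._istd[None, :, None, None]
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, grad):
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.dgamma[:] = (grad * self._xhat).sum(axis=(0, 2, 3))
        self.dbeta[:] = grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma[None, :, None, None]
        mean_g = g.mean(axis=(0, 2, 3), keepdims=True)
        mean_gx = (g * self._xhat).mean(axis=(0, 2, 3), keepdims=True)
        return (g - mean_g - self._xhat * mean_gx) * self._istd[None, :, None, None]


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2d(Layer):
    """2x2 max-pooling with stride 2."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(n, c, h // 2, w // 2, 4)
        self._arg = np.argmax(r, axis=-1)
        self._shape = x.shape
        return np.take_along_axis(r, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        n, c, h, w = self._shape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(flat, self._arg[..., None], grad[..., None], axis=-1)
        flat = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return flat.reshape(n, c, h, w)


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))
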