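"""Channel and spatial attention blocks.

Channel attention is a squeeze-and-excitation gate: global average pool,
a two-layer bottleneck MLP (reduction ratio 8) and a sigmoid produce one
weight in (0, 1) per channel, which multiplies the feature map.  Spatial
attention pools the channel axis (mean and max), convolves the 2-channel
map with a 7x7 kernel and gates every spatial position.  Both preserve
shape and are purely multiplicative, so zero input gives zero output.
"""

from __future__ import annotations

import numpy as np

from . import layers
from .layers import Conv2d, Layer, sigmoid

__all__ = ["ChannelAttention", "SpatialAttention"]


class ChannelAttention(Layer):
    def __init__(self, channels: int, reduction: int = 8, rng=None):
        rng = rng or np.random.default_rng(0)
        hidden = max(1, channels // reduction)
        self.W1 = rng.normal(0, np.sqrt(2.0 / channels), (hidden, channels)).astype(layers.DTYPE)
        self.b1 = np.zeros(hidden, dtype=layers.DTYPE)
        self.W2 = rng.normal(0, np.sqrt(2.0 / hidden), (channels, hidden)).astype(layers.DTYPE)
        self.b2 = np.zeros(channels, dtype=layers.DTYPE)
        self.dW1 = np.zeros_like(self.W1)
        self.db1 = np.zeros_like(self.b1)
        self.dW2 = np.zeros_like(self.W2)
        self.db2 = np.zeros_like(self.b2)

    def params(self):
        return [(self.W1, self.dW1), (self.b1, self.db1),
                (self.W2, self.dW2), (self.b2, self.db2)]

    def forward(self, x, train=True):
        self._x = x
        self._s = x.mean(axis=(2, 3))  # squeeze: (N, C)
        self._h = np.maximum(self._s @ self.W1.T + self.b1, 0.0)
        self._g = sigmoid(self._h @ self.W2.T + self.b2)  # (N, C) in (0, 1)
        return x * self._g[:, :, None, None]

    def backward(self, grad):
        x, g = self._x, self._g
        dx = grad * g[:, :, None, None]
        dg = (grad * x).sum(axis=(2, 3))  # (N, C)
        dz2 = dg * g * (1.0 - g)
        self.dW2[:] = dz2.T @ self._h
        self.db2[:] = dz2.sum(axis=0)
        dh = (dz2 @ self.W2) * (self._h > 0)
        self.dW1[:] = dh.T @ self._s
        self.db1[:] = dh.sum(axis=0)
        ds = dh @ self.W1  # (N, C)
        hw = x.shape[2] * x.shape[3]
        dx += ds[:, :, None, None] / hw
        return dx


class SpatialAttention(Layer):
    def __init__(self, kernel: int = 7, rng=None):
        self.conv = Conv2d(2, 1, kernel=kernel, rng=rng or np.random.default_rng(0))

    def params(self):
        return self.conv.params()

    def forward(self, x, train=True):
        self._x = x
        mean = x.mean(axis=1, keepdims=True)
        self._argmax = np.argmax(x, axis=1)
        mx = np.take_along_axis(x, self._argmax[:, None], axis=1)
        pooled = np.concatenate([mean, mx], axis=1)  # (N, 2, H, W)
        self._g = sigmoid(self.conv.forward(pooled, train))  # (N, 1, H, W)
        return x * self._g

    def backward(self, grad):
        x, g = self._x, self._g
        dx = grad * g
        dg = (grad * x).sum(axis=1, keepdims=True)
        dz = dg * g * (1.0 - g)
        dpooled = self.conv.backward(dz)
        c = x.shape[1]
        dx += dpooled[:, 0:1] / c  # mean-pool branch
        dmax = np.zeros_like(x)
        np.put_along_axis(dmax, self._argmax[:, None], dpooled[:, 1:2], axis=1)
        return dx + dmax
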