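"""Convolutional block attention (CBAM): sequential channel then spatial
attention gates applied to a feature map.

Channel attention squeezes the map by global average and max pooling, runs
both descriptors through a shared two-layer bottleneck MLP, and gates each
channel by the sigmoid of their sum.  Spatial attention stacks the
channel-wise mean and max into a 2-channel map, convolves it (7x7), and gates
each location by the sigmoid.  Both backward passes route the max-branch
gradient to the argmax element only.
"""

from __future__ import annotations

import numpy as np

from .core import Module
from .layers import Conv2d, Linear, ReLU


class ChannelAttention(Module):
    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 4) -> None:
        hidden = max(channels // reduction, 1)
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.relu = ReLU()
        self.fc2 = Linear(hidden, channels, rng=rng)

    def _mlp_forward(self, v: np.ndarray) -> tuple[np.ndarray, dict]:
        h1 = v @ self.fc1.w.value.T + self.fc1.b.value
        a1 = np.maximum(h1, 0.0)
        out = a1 @ self.fc2.w.value.T + self.fc2.b.value
        return out, {"v": v, "h1": h1, "a1": a1}

    def _mlp_backward(self, grad: np.ndarray, cache: dict) -> np.ndarray:
        self.fc2.w.grad += grad.T @ cache["a1"]
        self.fc2.b.grad += grad.sum(axis=0)
        da1 = grad @ self.fc2.w.value
        dh1 = da1 * (cache["h1"] > 0)
        self.fc1.w.grad += dh1.T @ cache["v"]
        self.fc1.b.grad += dh1.sum(axis=0)
        return dh1 @ self.fc1.w.value

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        avg = x.mean(axis=(2, 3))
        flat = x.reshape(n, c, h * w)
        self._argmax = flat.argmax(axis=2)
        mx = np.take_along_axis(flat, self._argmax[:, :, None], axis=2)[:, :, 0]
        z_avg, self._c_avg = self._mlp_forward(avg)
        z_max, self._c_max = self._mlp_forward(mx)
        self._s = 1.0 / (1.0 + np.exp(-(z_avg + z_max)))
        self._x = x
        return x * self._s[:, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x.shape
        dx = grad * self._s[:, :, None, None]
        ds = (grad * self._x).sum(axis=(2, 3))
        dz = ds * self._s * (1.0 - self._s)
        davg = self._mlp_backward(dz, self._c_avg)
        dmx = self._mlp_backward(dz, self._c_max)
        dx += davg[:, :, None, None] / (h * w)
        dflat = np.zeros((n, c, h * w), dtype=grad.dtype)
        np.put_along_axis(dflat, self._argmax[:, :, None], dmx[:, :, None], axis=2)
        dx += dflat.reshape(n, c, h, w)
        self._x = None
        return dx


class SpatialAttention(Module):
    def __init__(self, rng: np.random.Generator, k: int = 7) -> None:
        self.conv = Conv2d(2, 1, k=k, rng=rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        mean_c = x.mean(axis=1, keepdims=True)
        self._argmax = x.argmax(axis=1)
        max_c = np.take_along_axis(x, self._argmax[:, None, :, :], axis=1)
        z = self.conv.forward(np.concatenate([mean_c, max_c], axis=1))
        self._m = 1.0 / (1.0 + np.exp(-z))
        self._x = x
        return x * self._m

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x.shape
        dx = grad * self._m
        dm = (grad * self._x).sum(axis=1, keepdims=True)
        dz = dm * self._m * (1.0 - self._m)
        dcat = self.conv.backward(dz)
        dx += dcat[:, 0:1, :, :] / c
        dmax = np.zeros_like(self._x)
        np.put_along_axis(dmax, self._argmax[:, None, :, :], dcat[:, 1:2, :, :], axis=1)
        dx += dmax
        self._x = None
        return dx


class CBAM(Module):
    """Channel attention followed by spatial attention."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 reduction: int = 4, spatial_k: int = 7) -> None:
        self.channel = ChannelAttention(channels, rng=rng, reduction=reduction)
        self.spatial = SpatialAttention(rng=rng, k=spatial_k)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.spatial.forward(self.channel.forward(x))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.channel.backward(self.spatial.backward(grad))
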