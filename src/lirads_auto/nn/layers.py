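"""Numpy layers with hand-written backward passes.

Convolutions are stride-1 cross-correlations built on
``sliding_window_view`` + ``einsum``; spatial resolution changes go through
explicit 2x2 max-pooling and nearest-neighbour upsampling, which keeps every
backward pass a short closed form.  All tensors are NCHW.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import Module, Param, he_init


def _corr2d(x: np.ndarray, w: np.ndarray, pad: int) -> tuple[np.ndarray, np.ndarray]:
    """Cross-correlate x (N,Ci,H,W) with w (Co,Ci,k,k); returns (out, padded x)."""
    k = w.shape[-1]
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N,Ci,H',W',k,k)
    out = np.einsum("nchwij,ocij->nohw", win, w, optimize=True)
    return out, xp


class Conv2d(Module):
    """3x3 (or kxk) stride-1 convolution with 'same'-style zero padding."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, pad: int | None = None,
                 rng: np.random.Generator | None = None, bias: bool = True) -> None:
        rng = rng if rng is not None else np.random.default_rng(0)
        self.k = k
        self.pad = k // 2 if pad is None else pad
        self.w = Param(he_init(rng, (c_out, c_in, k, k), c_in * k * k), "conv.w")
        self.b = Param(np.zeros(c_out), "conv.b") if bias else None
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        out, self._xp = _corr2d(x, self.w.value, self.pad)
        if self.b is not None:
            out += self.b.value[None, :, None, None]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k, pad = self.k, self.pad
        win = sliding_window_view(self._xp, (k, k), axis=(2, 3))
        self.w.grad += np.einsum("nchwij,nohw->ocij", win, grad, optimize=True)
        if self.b is not None:
            self.b.grad += grad.sum(axis=(0, 2, 3))
        w_flip = self.w.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        dxp, _ = _corr2d(grad, w_flip, k - 1)
        if pad:
            dxp = dxp[:, :, pad:-pad, pad:-pad]
        self._xp = None
        return dxp


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Sigmoid(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._y * (1.0 - self._y)


class MaxPool2(Module):
    """2x2 max pooling, stride 2; gradient routed to the argmax element."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 needs even spatial dims, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = flat.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(flat, self._idx[..., None], grad[..., None], axis=-1)
        xr = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return xr.reshape(n, c, h, w)


class UpNearest2(Module):
    """Nearest-neighbour 2x upsampling; backward sums each 2x2 block."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Linear(Module):
    def __init__(self, d_in: int, d_out: int,
                 rng: np.random.Generator | None = None) -> None:
        rng = rng if rng is not None else np.random.default_rng(0)
        self.w = Param(he_init(rng, (d_out, d_in), d_in), "linear.w")
        self.b = Param(np.zeros(d_out), "linear.b")

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value


class GlobalAvgPool(Module):
    """(N,C,H,W) -> (N,C) spatial mean."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)


class Sequential(Module):
    def __init__(self, *modules: Module) -> None:
        self.modules = list(modules)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for m in self.modules:
            x = m.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for m in reversed(self.modules):
            grad = m.backward(grad)
        return grad


class ConvRelu(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 3) -> None:
        self.conv = Conv2d(c_in, c_out, k=k, rng=rng)
        self.act = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.act.forward(self.conv.forward(x))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.act.backward(grad))


class ResidualBlock(Module):
    """conv-relu-conv + identity (1x1 projection when channels change), relu;
    optionally followed by a CBAM attention block."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 attention: bool = False) -> None:
        self.conv1 = Conv2d(c_in, c_out, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, rng=rng)
        self.proj = Conv2d(c_in, c_out, k=1, rng=rng, bias=False) if c_in != c_out else None
        self.relu2 = ReLU()
        if attention:
            from .attention import CBAM

            self.cbam = CBAM(c_out, rng=rng)
        else:
            self.cbam = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        skip = self.proj.forward(x) if self.proj is not None else x
        out = self.relu2.forward(h + skip)
        if self.cbam is not None:
            out = self.cbam.forward(out)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.cbam is not None:
            grad = self.cbam.backward(grad)
        grad = self.relu2.backward(grad)
        d_skip = self.proj.backward(grad) if self.proj is not None else grad
        d_main = self.conv1.backward(self.relu1.backward(self.conv2.backward(grad)))
        return d_main + d_skip
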