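"""Minimal building blocks for the package's numpy neural networks.

A :class:`Param` couples a weight array with its gradient accumulator; a
:class:`Module` is anything with ``forward``/``backward`` and a flat list of
parameters; :class:`Adam` is the optimizer.  Layers cache whatever the
backward pass needs during ``forward`` and must therefore be used in strict
forward-then-backward order, one batch at a time — all the training loops in
this package do exactly that.

Everything runs in float64: the networks are small enough that the extra
width costs little, and it keeps the numerical gradient checks tight.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    """Base class: collects parameters from attributes and sub-modules."""

    def params(self) -> list[Param]:
        out: list[Param] = []
        for attr in self.__dict__.values():
            if isinstance(attr, Param):
                out.append(attr)
            elif isinstance(attr, Module):
                out.extend(attr.params())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        out.extend(item.params())
                    elif isinstance(item, Param):
                        out.append(item)
        return out

    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    # -- serialization ------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.value for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        if len(state) != len(params):
            raise ValueError(
                f"state has {len(state)} arrays, model has {len(params)} parameters"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=np.float64)
            if arr.shape != p.value.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.value[...] = arr

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
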