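"""Minimal neural-network layers over the autodiff :class:`Tensor`.

Layers hold their parameters as ``Tensor(requires_grad=True)`` attributes;
:meth:`Module.parameters` walks the attribute tree so optimizers and
checkpoint serialization see every weight exactly once, in a stable order.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in self.__dict__.values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state size mismatch")
        for p, arr in zip(params, state):
            p.data = np.asarray(arr, dtype=float).reshape(p.data.shape)


def _collect(value):
    if isinstance(value, Tensor) and value.requires_grad:
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for item in value:
            yield from _collect(item)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((in_features, out_features))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / (in_features + out_features)),
                           (in_features, out_features))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    """Stride-1 grouped 2-D convolution with 'same' zero padding by default."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: tuple[int, int],
                 rng: np.random.Generator, groups: int = 1,
                 padding: tuple[int, int] | None = None, zero_init: bool = False):
        kh, kw = kernel_size
        fan_in = (in_channels // groups) * kh * kw
        w = np.zeros((out_channels, in_channels // groups, kh, kw)) if zero_init else \
            rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels // groups, kh, kw))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.padding = ((kh - 1) // 2, (kw - 1) // 2) if padding is None else padding
        self.groups = groups

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, padding=self.padding, groups=self.groups)


class Conv1d(Module):
    """1-D convolution on (B, C, L) maps, implemented on the 2-D kernel path."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, groups: int = 1, zero_init: bool = False):
        self.conv = Conv2d(in_channels, out_channels, (1, kernel_size), rng,
                           groups=groups, zero_init=zero_init)

    def __call__(self, x: Tensor) -> Tensor:
        B, C, L = x.shape
        out = self.conv(x.reshape(B, C, 1, L))
        _, Co, _, Lo = out.shape
        return out.reshape(B, Co, Lo)


class Embedding(Module):
    def __init__(self, num_embeddings: int, dim: int, rng: np.random.Generator):
        self.weight = Tensor(rng.normal(0.0, 0.02, (num_embeddings, dim)),
                             requires_grad=True)

    def __call__(self, indices: np.ndarray) -> Tensor:
        return self.weight[np.asarray(indices, dtype=int)]


def sinusoidal_embedding(t: np.ndarray, dim: int, max_period: float = 10000.0) -> np.ndarray:
    """Sinusoidal time embedding: first half sines, second half cosines at
    geometric frequencies; t=0 maps to (0,…,0, 1,…,1)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    half = dim // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half) / max(half - 1, 1))
    args = t[:, None] * freqs[None, :]
    return np.concatenate([np.sin(args), np.cos(args)], axis=1)
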