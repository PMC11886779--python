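"""Trainable layers and the Adam optimizer used by the DTI model."""
from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import DTYPE, Tensor


class Module:
    """Parameter container with recursive collection and (de)serialisation."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(f"state has {len(state)} arrays, model has {len(params)}")
        for i, p in enumerate(params):
            p.data = np.asarray(state[f"p{i}"], dtype=DTYPE).reshape(p.shape)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _collect(value):
    if isinstance(value, Tensor) and value.requires_grad:
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)
    elif isinstance(value, dict):
        for v in value.values():
            yield from _collect(v)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(DTYPE)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        self.weight = ag.parameter(glorot(rng, in_dim, out_dim), name=f"linear{in_dim}x{out_dim}.W")
        self.bias = ag.parameter(np.zeros(out_dim, dtype=DTYPE), name="b") if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gain = ag.parameter(np.ones(dim, dtype=DTYPE), name="ln.g")
        self.shift = ag.parameter(np.zeros(dim, dtype=DTYPE), name="ln.b")
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gain + self.shift


class EmbeddingTable(Module):
    """Integer-indexed lookup table (used for pocket-rank positions)."""

    def __init__(self, size: int, dim: int, zero_init: bool = True,
                 rng: np.random.Generator | None = None):
        if zero_init:
            init = np.zeros((size, dim), dtype=DTYPE)
        else:
            assert rng is not None
            init = (rng.standard_normal((size, dim)) * 0.02).astype(DTYPE)
        self.table = ag.parameter(init, name=f"embed{size}x{dim}")
        self.size = size

    def __call__(self, index: np.ndarray) -> Tensor:
        index = np.asarray(index)
        if index.max(initial=0) >= self.size:
            raise ValueError(f"position {int(index.max())} exceeds table size {self.size}")
        flat = ag.gather_rows(self.table, index.reshape(-1))
        return flat.reshape(*index.shape, self.table.shape[1])


class MLP(Module):
    """Plain ReLU multilayer perceptron."""

    def __init__(self, widths: list[int], rng: np.random.Generator):
        self.layers = [Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = ag.relu(x)
        return x


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
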