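"""Layer primitives built on the autodiff engine.

Initialization is fan-in uniform from an explicit ``numpy`` generator so that
every model is reproducible to the bit given a seed.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np

from ..errors import ConfigError, InputError
from .autodiff import Tensor, concatenate


class Module:
    """Container tracking trainable parameters in registration order."""

    def __init__(self) -> None:
        self._params: list[tuple[str, Tensor]] = []
        self._children: list[tuple[str, "Module"]] = []
        self.training = True

    def register(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params.append((name, t))
        return t

    def add_child(self, name: str, child: "Module") -> "Module":
        self._children.append((name, child))
        return child

    def parameters(self) -> list[Tensor]:
        out = [t for _, t in self._params]
        for _, c in self._children:
            out.extend(c.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + n, t) for n, t in self._params]
        for name, c in self._children:
            out.extend(c.named_parameters(prefix + name + "."))
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self) -> None:
        self.training = True
        for _, c in self._children:
            c.train()

    def eval(self) -> None:
        self.training = False
        for _, c in self._children:
            c.eval()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {n: t.data.copy() for n, t in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for n, t in self.named_parameters():
            t.data = state[n].copy()


def fan_in_uniform(rng: np.random.Generator, shape: tuple) -> np.ndarray:
    bound = 1.0 / np.sqrt(shape[0]) if shape[0] > 0 else 1.0
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = self.register("weight", fan_in_uniform(rng, (d_in, d_out)))
        self.bias = self.register("bias", np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.weight.shape[0]:
            raise InputError(
                f"linear layer expected input dim {self.weight.shape[0]}, got {x.shape[-1]}")
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = self.register("weight", rng.normal(0.0, 1.0 / np.sqrt(dim),
                                                         size=(n_tokens, dim)))

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.weight.gather(np.asarray(ids, dtype=int))


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = self.register("gamma", np.ones(dim))
        self.beta = self.register("beta", np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2.0).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class BatchNorm(Module):
    """Normalization over the batch axis using batch statistics (no running
    averages; evaluation also uses the statistics of the evaluated batch)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = self.register("gamma", np.ones(dim))
        self.beta = self.register("beta", np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=0, keepdims=True)
        var = ((x - mu) ** 2.0).mean(axis=0, keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout driven by an explicit generator; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ConfigError(f"dropout must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * mask


ACTIVATIONS: dict[str, Callable[[Tensor], Tensor]] = {
    "relu": Tensor.relu,
    "silu": Tensor.silu,
    "tanh": Tensor.tanh,
    "sigmoid": Tensor.sigmoid,
    "identity": lambda x: x,
}


def make_norm(kind: str, dim: int) -> Optional[Module]:
    if kind in (None, "none"):
        return None
    if kind == "layer":
        return LayerNorm(dim)
    if kind == "batch":
        return BatchNorm(dim)
    raise ConfigError(f"unknown normalization {kind!r}")


class FeedForward(Module):
    """Stack of Linear + activation (+ dropout/norm) blocks with a linear head."""

    def __init__(self, d_in: int, width: int, depth: int, d_out: int,
                 rng: np.random.Generator, activation: str = "relu",
                 dropout: float = 0.0, normalization: str = "none"):
        super().__init__()
        self.act = ACTIVATIONS[activation]
        self.blocks: list[tuple[Linear, Optional[Module], Optional[Dropout]]] = []
        d = d_in
        for i in range(depth):
            lin = self.add_child(f"lin{i}", Linear(d, width, rng))
            norm = make_norm(normalization, width)
            if norm is not None:
                self.add_child(f"norm{i}", norm)
            drop = Dropout(dropout, rng) if dropout > 0 else None
            if drop is not None:
                self.add_child(f"drop{i}", drop)
            self.blocks.append((lin, norm, drop))
            d = width
        self.head = self.add_child("head", Linear(d, d_out, rng))

    def __call__(self, x: Tensor) -> Tensor:
        for lin, norm, drop in self.blocks:
            x = lin(x)
            if norm is not None:
                x = norm(x)
            x = self.act(x)
            if drop is not None:
                x = drop(x)
        return self.head(x)


class GRUCell(Module):
    """Gated recurrent cell; one step over a (batch, dim) slice."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        super().__init__()
        self.wz = self.add_child("wz", Linear(d_in + d_hidden, d_hidden, rng))
        self.wr = self.add_child("wr", Linear(d_in + d_hidden, d_hidden, rng))
        self.wh = self.add_child("wh", Linear(d_in + d_hidden, d_hidden, rng))

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        xh = concatenate([x, h], axis=-1)
        z = self.wz(xh).sigmoid()
        r = self.wr(xh).sigmoid()
        cand = self.wh(concatenate([x, r * h], axis=-1)).tanh()
        return (1.0 - z) * h + z * cand
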