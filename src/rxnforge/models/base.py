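"""Model registry and shared building blocks.

Every architecture follows the same composition — an encoder, message-passing
or sequence layers, a pooling function, and a prediction head — and registers
itself by name so that pipelines swap models through configuration alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from ..errors import ConfigError
from ..nn.autodiff import Tensor
from ..nn.layers import Module


@dataclass
class ModelConfig:
    """Hyperparameters shared by all architectures (3D-specific fields are
    ignored by non-3D models)."""

    architecture: str = "dmpnn"
    width: int = 64
    depth: int = 3
    dropout: float = 0.0
    normalization: str = "none"          # none | batch | layer
    pooling: str = "sum"                 # sum | mean | max
    head_depth: int = 1
    activation: Optional[str] = None     # default depends on architecture
    # 3D-specific
    cutoff: float = 5.0                  # Angstrom, radius-graph threshold
    n_rbf: int = 8                       # radial basis functions
    n_blocks: int = 3                    # interaction blocks
    n_angular: int = 6                   # angular (cosine) basis size
    # sequence-specific
    embedding_dim: int = 64
    molecule_encoder: str = "gru"        # gru | none (order-insensitive)
    extras: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.width < 1 or self.depth < 0 or self.head_depth < 0:
            raise ConfigError("width must be >= 1, depth and head_depth >= 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError(f"dropout must be in [0,1), got {self.dropout}")
        if self.pooling not in ("sum", "mean", "max"):
            raise ConfigError(f"unknown pooling {self.pooling!r}")
        if self.architecture in ("dimereaction",) and self.cutoff <= 0:
            raise ConfigError(f"cutoff must be positive, got {self.cutoff}")


MODEL_REGISTRY: dict[str, Callable] = {}


def register_model(name: str) -> Callable:
    def deco(cls):
        MODEL_REGISTRY[name] = cls
        return cls
    return deco


def build_model(cfg: ModelConfig, seed: int = 0, **meta):
    """Instantiate a registered architecture from its config and a seed."""
    cfg.validate()
    try:
        cls = MODEL_REGISTRY[cfg.architecture]
    except KeyError:
        raise ConfigError(
            f"unknown architecture {cfg.architecture!r}; registered: "
            f"{sorted(MODEL_REGISTRY)}") from None
    if isinstance(cls, str):  # registry stub
        raise ConfigError(f"architecture {cfg.architecture!r} is a registry stub: {cls}")
    return cls(cfg, rng=np.random.default_rng(seed), **meta)


def register_stub(name: str, note: str) -> None:
    MODEL_REGISTRY[name] = note


for _name in ("gatedgcn", "gat", "gatv2", "gine", "graphgps", "pna"):
    register_stub(_name, "planned graph-convolution variant; contribute via the registry")


def _segment_max(x: Tensor, ids: np.ndarray, n: int) -> Tensor:
    """Per-segment feature-wise max; gradient routes to the argmax rows."""
    ids = np.asarray(ids, dtype=int)
    data = np.full((n,) + x.shape[1:], -np.inf)
    np.maximum.at(data, ids, x.data)
    data[np.isneginf(data)] = 0.0
    # argmax bookkeeping: first row achieving the max in each segment
    arg = np.zeros((n,) + x.shape[1:], dtype=int)
    seen = np.zeros((n,) + x.shape[1:], dtype=bool)
    for row in range(x.shape[0]):
        s = ids[row]
        better = (~seen[s]) | (x.data[row] > x.data[arg[s], np.arange(x.shape[1])])
        arg[s] = np.where(better, row, arg[s])
        seen[s] |= better

    def back(g: np.ndarray) -> None:
        full = np.zeros_like(x.data)
        cols = np.arange(x.shape[1])
        for s in range(n):
            if seen[s].any():
                np.add.at(full, (arg[s], cols), g[s] * seen[s])
        x._accum(full)
    return Tensor._make(data, (x,), back)


def pool_nodes(x: Tensor, graph_ids: np.ndarray, n_graphs: int, mode: str) -> Tensor:
    """Pool per-node (or per-edge) states to per-graph vectors."""
    if mode == "sum":
        return x.segment_sum(graph_ids, n_graphs)
    if mode == "mean":
        counts = np.bincount(np.asarray(graph_ids, dtype=int), minlength=n_graphs)
        counts = np.maximum(counts, 1).astype(float)
        return x.segment_sum(graph_ids, n_graphs) * (1.0 / counts)[:, None]
    if mode == "max":
        return _segment_max(x, graph_ids, n_graphs)
    raise ConfigError(f"unknown pooling {mode!r}")


class ReactionModel(Module):
    """Base class: subclasses implement ``forward(batch) -> Tensor`` of shape (B,)."""

    def forward(self, batch) -> Tensor:  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, batch) -> Tensor:
        return self.forward(batch)
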