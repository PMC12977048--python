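"""Multilayer perceptron over differential reaction fingerprints."""

from __future__ import annotations

import numpy as np

from ..errors import InputError
from ..nn.autodiff import Tensor
from ..nn.layers import FeedForward
from .base import ModelConfig, ReactionModel, register_model


@register_model("mlp")
class FingerprintMLP(ReactionModel):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator, n_bits: int = 2048,
                 n_outputs: int = 1):
        super().__init__()
        self.n_bits = n_bits
        self.n_outputs = n_outputs
        self.net = self.add_child("net", FeedForward(
            n_bits, cfg.width, cfg.depth, n_outputs, rng,
            activation=cfg.activation or "relu", dropout=cfg.dropout,
            normalization=cfg.normalization))

    def forward(self, batch: np.ndarray) -> Tensor:
        x = np.asarray(batch, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.n_bits:
            raise InputError(f"expected (batch, {self.n_bits}) fingerprints, got {x.shape}")
        out = self.net(Tensor(x))
        return out.reshape(x.shape[0]) if self.n_outputs == 1 else out
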