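"""Hierarchical attention network over tokenized reaction SMILES.

Two-level hierarchy: a bidirectional GRU with additive attention encodes each
molecule from its tokens, then a molecule-level encoder (BiGRU, or identity
for an order-insensitive variant) with a second attention pools molecules into
a reaction embedding fed to a linear head.
"""

from __future__ import annotations

import numpy as np

from ..errors import InputError
from ..nn.autodiff import Tensor, concatenate, softmax, stack
from ..nn.layers import Embedding, FeedForward, GRUCell, Linear, Module
from ..representations import TokenSequence
from .base import ModelConfig, ReactionModel, register_model

PAD_ID = 1


class AdditiveAttention(Module):
    """score_t = v^T tanh(W u_t); weights softmax-normalized per group."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.proj = self.add_child("proj", Linear(dim, dim, rng))
        self.v = self.add_child("v", Linear(dim, 1, rng, bias=False))

    def scores(self, u: Tensor) -> Tensor:
        return self.v(self.proj(u).tanh())


class BiGRU(Module):
    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = self.add_child("fwd", GRUCell(d_in, d_hidden, rng))
        self.bwd = self.add_child("bwd", GRUCell(d_in, d_hidden, rng))
        self.d_hidden = d_hidden

    def __call__(self, steps: list[Tensor], mask: np.ndarray) -> list[Tensor]:
        """steps: length-L list of (M, d_in); mask (M, L).  Returns per-step
        (M, 2*d_hidden) states; padded positions keep the previous state."""
        m_rows = steps[0].shape[0]
        length = len(steps)
        h = Tensor(np.zeros((m_rows, self.d_hidden)))
        states_f = []
        for t in range(length):
            upd = self.fwd(steps[t], h)
            mt = mask[:, t:t + 1]
            h = upd * mt + h * (1.0 - mt)
            states_f.append(h)
        h = Tensor(np.zeros((m_rows, self.d_hidden)))
        states_b: list = [None] * length
        for t in reversed(range(length)):
            upd = self.bwd(steps[t], h)
            mt = mask[:, t:t + 1]
            h = upd * mt + h * (1.0 - mt)
            states_b[t] = h
        return [concatenate([f, b], axis=1) for f, b in zip(states_f, states_b)]


def _attend(states: list[Tensor], mask: np.ndarray, att: AdditiveAttention) -> Tensor:
    """Masked additive-attention pooling over the time axis."""
    scores = stack([att.scores(s).reshape(s.shape[0]) for s in states], axis=1)
    scores = scores + (1.0 - mask) * -1e9
    alpha = softmax(scores, axis=1)
    pooled = None
    for t, s in enumerate(states):
        term = s * alpha[:, t].reshape(s.shape[0], 1)
        pooled = term if pooled is None else pooled + term
    return pooled


@register_model("han")
class HAN(ReactionModel):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 vocab_size: int, n_outputs: int = 1):
        super().__init__()
        self.cfg = cfg
        d_emb, h = cfg.embedding_dim, cfg.width
        self.embedding = self.add_child("embedding", Embedding(vocab_size, d_emb, rng))
        self.token_rnn = self.add_child("token_rnn", BiGRU(d_emb, h, rng))
        self.token_att = self.add_child("token_att", AdditiveAttention(2 * h, rng))
        if cfg.molecule_encoder == "gru":
            self.mol_rnn = self.add_child("mol_rnn", BiGRU(2 * h, h, rng))
            d_mol = 2 * h
        elif cfg.molecule_encoder == "none":
            self.mol_rnn = None
            d_mol = 2 * h
        else:
            raise InputError(f"unknown molecule_encoder {cfg.molecule_encoder!r}")
        self.mol_att = self.add_child("mol_att", AdditiveAttention(d_mol, rng))
        self.head = self.add_child("head", FeedForward(
            d_mol, cfg.width, cfg.head_depth, n_outputs, rng,
            activation=cfg.activation or "relu", dropout=cfg.dropout,
            normalization=cfg.normalization))
        self.n_outputs = n_outputs

    # -- batching helpers ----------------------------------------------------

    @staticmethod
    def _molecule_ids(batch: list[TokenSequence]) -> tuple[list[list[int]], np.ndarray]:
        mols, rxn_of_mol = [], []
        for r, seq in enumerate(batch):
            if seq.vocab_ids is None:
                raise InputError("token sequence has no vocabulary ids; encode first")
            if not seq.tokens:
                raise InputError("empty token sequence")
            for start, end in seq.molecule_boundaries:
                mols.append(seq.vocab_ids[start:end])
            if not seq.molecule_boundaries:
                raise InputError("token sequence has no molecules")
            rxn_of_mol.extend([r] * len(seq.molecule_boundaries))
        return mols, np.asarray(rxn_of_mol, dtype=int)

    def _encode_molecules(self, mols: list[list[int]]) -> Tensor:
        m, length = len(mols), max(len(ids) for ids in mols)
        ids = np.full((m, length), PAD_ID, dtype=int)
        mask = np.zeros((m, length))
        for i, seq in enumerate(mols):
            ids[i, :len(seq)] = seq
            mask[i, :len(seq)] = 1.0
        emb = self.embedding(ids.reshape(-1))
        steps = [emb.gather(np.arange(m) * length + t) for t in range(length)]
        states = self.token_rnn(steps, mask)
        return _attend(states, mask, self.token_att)

    def forward(self, batch: list[TokenSequence]) -> Tensor:
        mols, rxn_of_mol = self._molecule_ids(batch)
        mol_emb = self._encode_molecules(mols)
        n_rxn = len(batch)
        counts = np.bincount(rxn_of_mol, minlength=n_rxn)
        l_mol = int(counts.max())
        # pad with an all-zero molecule row at index len(mols)
        padded = concatenate([mol_emb, Tensor(np.zeros((1, mol_emb.shape[1])))], axis=0)
        idx = np.full((n_rxn, l_mol), len(mols), dtype=int)
        mask = np.zeros((n_rxn, l_mol))
        pos = np.zeros(n_rxn, dtype=int)
        for mol_i, r in enumerate(rxn_of_mol):
            idx[r, pos[r]] = mol_i
            mask[r, pos[r]] = 1.0
            pos[r] += 1
        steps = [padded.gather(idx[:, t]) for t in range(l_mol)]
        if self.mol_rnn is not None:
            states = self.mol_rnn(steps, mask)
        else:
            states = steps
        rxn_emb = _attend(states, mask, self.mol_att)
        out = self.head(rxn_emb)
        return out.reshape(n_rxn) if self.n_outputs == 1 else out
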