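"""Graph networks on the condensed graph of reaction.

Contains the batched graph collation shared by all graph architectures, the
directed message passing network (hidden states on directed edges, reverse
edge excluded from each update) and a degree-normalized graph convolution as
the pluggable reference for further GNN variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import InputError
from ..nn.autodiff import Tensor, concatenate
from ..nn.layers import ACTIVATIONS, FeedForward, Linear
from ..representations import ReactionGraph
from .base import ModelConfig, ReactionModel, pool_nodes, register_model


@dataclass
class GraphBatch:
    node_x: np.ndarray      # (N, d_node)
    edge_index: np.ndarray  # (2, E) global node ids
    edge_attr: np.ndarray   # (E, d_edge)
    rev: np.ndarray         # (E,) index of each edge's reverse
    node_graph: np.ndarray  # (N,) graph id per node
    n_graphs: int

    @property
    def src(self) -> np.ndarray:
        return self.edge_index[0]

    @property
    def dst(self) -> np.ndarray:
        return self.edge_index[1]


def collate_graphs(graphs: list[ReactionGraph]) -> GraphBatch:
    """Concatenate graphs into one disjoint-union graph with offset indices."""
    if not graphs:
        raise InputError("empty graph batch")
    xs, eis, eas, revs, gids = [], [], [], [], []
    n_off = e_off = 0
    for gid, g in enumerate(graphs):
        if g.n_nodes == 0:
            raise InputError(f"graph {gid} in batch has zero nodes")
        xs.append(g.node_features)
        eis.append(g.edge_index + n_off)
        eas.append(g.edge_features)
        revs.append(g.reverse_index() + e_off)
        gids.append(np.full(g.n_nodes, gid))
        n_off += g.n_nodes
        e_off += g.n_edges
    return GraphBatch(np.vstack(xs), np.hstack(eis).astype(int)
                      if eis else np.zeros((2, 0), int),
                      np.vstack(eas), np.hstack(revs).astype(int),
                      np.hstack(gids).astype(int), len(graphs))


@register_model("dmpnn")
class DMPNN(ReactionModel):
    """Directed message passing network (chemprop-style recursion).

    The hidden state of directed edge ``v -> w`` is updated from the sum of the
    states of edges ``u -> v`` with ``u != w`` (the reverse edge is excluded),
    added to the initial edge state, through a shared linear map with a
    nonlinearity.  Atom states aggregate incoming edge states and are pooled
    over each graph.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 d_node: int, d_edge: int, n_outputs: int = 1):
        super().__init__()
        self.cfg = cfg
        self.act = ACTIVATIONS[cfg.activation or "relu"]
        w = cfg.width
        self.w_in = self.add_child("w_in", Linear(d_node + d_edge, w, rng))
        self.w_h = self.add_child("w_h", Linear(w, w, rng, bias=False))
        self.w_atom = self.add_child("w_atom", Linear(d_node + w, w, rng))
        self.head = self.add_child("head", FeedForward(
            w, w, cfg.head_depth, n_outputs, rng,
            activation=cfg.activation or "relu", dropout=cfg.dropout,
            normalization=cfg.normalization))
        self.n_outputs = n_outputs

    def edge_states(self, batch: GraphBatch) -> Tensor:
        """Final directed-edge hidden states (exposed for oracle tests)."""
        x = Tensor(batch.node_x)
        e = Tensor(batch.edge_attr)
        n_nodes = batch.node_x.shape[0]
        h0 = self.act(self.w_in(concatenate([x.gather(batch.src), e], axis=1))) \
            if batch.edge_attr.shape[0] else Tensor(np.zeros((0, self.cfg.width)))
        h = h0
        for _ in range(self.cfg.depth):
            node_in = h.segment_sum(batch.dst, n_nodes)
            m = node_in.gather(batch.src) - h.gather(batch.rev)
            h = self.act(h0 + self.w_h(m))
        return h

    def forward(self, graphs: list[ReactionGraph]) -> Tensor:
        batch = graphs if isinstance(graphs, GraphBatch) else collate_graphs(graphs)
        n_nodes = batch.node_x.shape[0]
        h = self.edge_states(batch)
        incoming = h.segment_sum(batch.dst, n_nodes)
        node_h = self.act(self.w_atom(concatenate([Tensor(batch.node_x), incoming], axis=1)))
        pooled = pool_nodes(node_h, batch.node_graph, batch.n_graphs, self.cfg.pooling)
        out = self.head(pooled)
        return out.reshape(batch.n_graphs) if self.n_outputs == 1 else out


@register_model("gcn")
class GCN(ReactionModel):
    """Graph convolution with symmetric degree normalization.

    Layer rule: ``h_v' = act(W_self h_v + W_nbr sum_u h_u / sqrt(d_u d_v))``
    over bonded neighbors ``u``; demonstrates the encoder/layers/pooling/head
    composition that further GNN variants plug into.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 d_node: int, d_edge: int = 0, n_outputs: int = 1):
        super().__init__()
        self.cfg = cfg
        self.act = ACTIVATIONS[cfg.activation or "relu"]
        w = cfg.width
        self.encoder = self.add_child("encoder", Linear(d_node, w, rng))
        self.w_self = [self.add_child(f"w_self{i}", Linear(w, w, rng))
                       for i in range(cfg.depth)]
        self.w_nbr = [self.add_child(f"w_nbr{i}", Linear(w, w, rng, bias=False))
                      for i in range(cfg.depth)]
        self.head = self.add_child("head", FeedForward(
            w, w, cfg.head_depth, n_outputs, rng,
            activation=cfg.activation or "relu", dropout=cfg.dropout,
            normalization=cfg.normalization))
        self.n_outputs = n_outputs

    def forward(self, graphs: list[ReactionGraph]) -> Tensor:
        batch = graphs if isinstance(graphs, GraphBatch) else collate_graphs(graphs)
        n_nodes = batch.node_x.shape[0]
        deg = np.bincount(batch.dst, minlength=n_nodes).astype(float)
        coef = (1.0 / np.sqrt(np.maximum(deg[batch.src], 1.0)
                              * np.maximum(deg[batch.dst], 1.0)))
        h = self.act(self.encoder(Tensor(batch.node_x)))
        for w_self, w_nbr in zip(self.w_self, self.w_nbr):
            msg = (h.gather(batch.src) * coef[:, None]).segment_sum(batch.dst, n_nodes)
            h = self.act(w_self(h) + w_nbr(msg))
        pooled = pool_nodes(h, batch.node_graph, batch.n_graphs, self.cfg.pooling)
        out = self.head(pooled)
        return out.reshape(batch.n_graphs) if self.n_outputs == 1 else out
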