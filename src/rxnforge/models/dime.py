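"""Directional 3D message passing on reactant/TS geometry pairs.

A shared-parameter encoder embeds each geometry: a radius graph is built from
interatomic distances, distances enter through a sinusoidal radial basis and
angles between incident edges through a cosine angular basis, and a configured
number of directional interaction blocks propagate edge messages before
pooling to a fixed-length graph embedding.  The prediction head consumes the
difference ``embedding(TS) - embedding(R)``, so identical geometries map to
``head(0)`` and the whole model is E(3)-invariant by construction (only
distances and angles enter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..errors import ConfigError, InputError
from ..nn.autodiff import Tensor, concatenate
from ..nn.layers import ACTIVATIONS, Embedding, FeedForward, Linear
from ..representations import GeometryPair
from .base import ModelConfig, ReactionModel, pool_nodes, register_model

ELEMENTS_3D = ("H", "C", "N", "O", "F", "S", "Cl", "Br")  # + "other"


def element_ids(elements: list[str]) -> np.ndarray:
    return np.array([ELEMENTS_3D.index(e) if e in ELEMENTS_3D else len(ELEMENTS_3D)
                     for e in elements], dtype=int)


@dataclass
class GeometryGraph:
    """Radius graph of a batch of geometries with precomputed invariant bases."""

    z: np.ndarray          # (N,) element ids
    node_graph: np.ndarray  # (N,) geometry id
    src: np.ndarray        # (E,)
    dst: np.ndarray        # (E,)
    rbf: np.ndarray        # (E, n_rbf)
    t_src: np.ndarray      # (T,) edge index of k->j
    t_dst: np.ndarray      # (T,) edge index of j->i
    ang: np.ndarray        # (T, n_angular)
    n_graphs: int


def _radial_basis(d: np.ndarray, cutoff: float, n_rbf: int) -> np.ndarray:
    """Sinusoidal (spherical-Bessel l=0) radial basis sin(k pi d/c)/d."""
    k = np.arange(1, n_rbf + 1)
    return np.sqrt(2.0 / cutoff) * np.sin(k[None, :] * np.pi * d[:, None] / cutoff) \
        / np.maximum(d[:, None], 1e-10)


def build_geometry_graph(pairs: list[tuple[list[str], np.ndarray]], cutoff: float,
                         n_rbf: int, n_angular: int) -> GeometryGraph:
    """Collate (elements, coords) geometries into one batched radius graph."""
    if cutoff <= 0:
        raise ConfigError(f"cutoff must be positive, got {cutoff}")
    zs, gids, srcs, dsts, dists, vecs = [], [], [], [], [], []
    n_off = 0
    for gid, (elements, coords) in enumerate(pairs):
        coords = np.asarray(coords, dtype=float)
        n = len(elements)
        zs.append(element_ids(elements))
        gids.append(np.full(n, gid))
        diff = coords[None, :, :] - coords[:, None, :]
        dist = np.linalg.norm(diff, axis=-1)
        mask = (dist < cutoff) & ~np.eye(n, dtype=bool)
        isolated = ~mask.any(axis=1) if n > 1 else np.ones(n, dtype=bool)
        if n > 1 and isolated.any():
            warnings.warn(f"geometry {gid}: {int(isolated.sum())} atom(s) have no "
                          f"neighbor within the {cutoff} A cutoff")
        src, dst = np.nonzero(mask)
        srcs.append(src + n_off)
        dsts.append(dst + n_off)
        dists.append(dist[src, dst])
        vecs.append(diff[src, dst])  # x_dst - x_src
        n_off += n
    z = np.concatenate(zs)
    node_graph = np.concatenate(gids).astype(int)
    src = np.concatenate(srcs).astype(int) if srcs else np.zeros(0, int)
    dst = np.concatenate(dsts).astype(int) if dsts else np.zeros(0, int)
    dist = np.concatenate(dists) if dists else np.zeros(0)
    vec = np.vstack(vecs) if vecs else np.zeros((0, 3))
    rbf = _radial_basis(dist, cutoff, n_rbf)

    # triplets: edge e = (j -> i); incoming f = (k -> j) with k != i
    by_dst: dict[int, list[int]] = {}
    for e in range(len(src)):
        by_dst.setdefault(int(dst[e]), []).append(e)
    t_src, t_dst, cos_t = [], [], []
    for e in range(len(src)):
        j, i = int(src[e]), int(dst[e])
        for f in by_dst.get(j, ()):
            if int(src[f]) == i:
                continue  # exclude the reverse direction k == i
            a = vec[e]          # x_i - x_j
            b = -vec[f]         # x_k - x_j
            c = np.dot(a, b) / max(np.linalg.norm(a) * np.linalg.norm(b), 1e-10)
            t_src.append(f)
            t_dst.append(e)
            cos_t.append(np.clip(c, -1.0, 1.0))
    theta = np.arccos(np.asarray(cos_t)) if cos_t else np.zeros(0)
    ang = np.cos(np.arange(n_angular)[None, :] * theta[:, None]) \
        if len(theta) else np.zeros((0, n_angular))
    return GeometryGraph(z, node_graph, src, dst, rbf,
                         np.asarray(t_src, int), np.asarray(t_dst, int), ang,
                         len(pairs))


@register_model("dimereaction")
class DimeReaction(ReactionModel):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator, n_outputs: int = 1):
        super().__init__()
        if cfg.cutoff <= 0:
            raise ConfigError(f"cutoff must be positive, got {cfg.cutoff}")
        self.cfg = cfg
        self.act = ACTIVATIONS[cfg.activation or "silu"]
        w = cfg.width
        self.embedding = self.add_child("embedding",
                                        Embedding(len(ELEMENTS_3D) + 1, w, rng))
        self.w_edge = self.add_child("w_edge", Linear(2 * w + cfg.n_rbf, w, rng))
        self.blocks = []
        for b in range(cfg.n_blocks):
            blk = {
                "w_msg": self.add_child(f"blk{b}.w_msg", Linear(w, w, rng)),
                "w_rbf": self.add_child(f"blk{b}.w_rbf", Linear(cfg.n_rbf, w, rng, bias=False)),
                "w_ang": self.add_child(f"blk{b}.w_ang", Linear(cfg.n_angular, w, rng, bias=False)),
                "w_upd": self.add_child(f"blk{b}.w_upd", Linear(w, w, rng)),
            }
            self.blocks.append(blk)
        self.w_atom = self.add_child("w_atom", Linear(2 * w, w, rng))
        self.head = self.add_child("head", FeedForward(
            w, w, cfg.head_depth, n_outputs, rng,
            activation=cfg.activation or "silu", dropout=cfg.dropout,
            normalization=cfg.normalization))
        self.n_outputs = n_outputs

    def embed_geometries(self, graph: GeometryGraph) -> Tensor:
        """Fixed-length embedding per geometry, invariant to rigid motions."""
        w = self.cfg.width
        emb = self.embedding(graph.z)
        n_nodes = len(graph.z)
        n_edges = len(graph.src)
        if n_edges:
            rbf = Tensor(graph.rbf)
            h0 = self.act(self.w_edge(concatenate(
                [emb.gather(graph.src), emb.gather(graph.dst), rbf], axis=1)))
            h = h0
            ang = Tensor(graph.ang)
            for blk in self.blocks:
                if len(graph.t_dst):
                    tri = (blk["w_msg"](h).gather(graph.t_src)
                           * blk["w_rbf"](rbf).gather(graph.t_dst)
                           * blk["w_ang"](ang))
                    agg = tri.segment_sum(graph.t_dst, n_edges)
                else:
                    agg = Tensor(np.zeros((n_edges, w)))
                h = self.act(h0 + blk["w_upd"](h + agg))
            atom_in = h.segment_sum(graph.dst, n_nodes)
        else:
            atom_in = Tensor(np.zeros((n_nodes, w)))
        atom = self.act(self.w_atom(concatenate([emb, atom_in], axis=1)))
        return pool_nodes(atom, graph.node_graph, graph.n_graphs, self.cfg.pooling)

    def forward(self, batch: list[GeometryPair]) -> Tensor:
        if not batch:
            raise InputError("empty geometry batch")
        cfg = self.cfg
        g_r = build_geometry_graph([(p.elements, p.r_coords) for p in batch],
                                   cfg.cutoff, cfg.n_rbf, cfg.n_angular)
        g_ts = build_geometry_graph([(p.elements, p.ts_coords) for p in batch],
                                    cfg.cutoff, cfg.n_rbf, cfg.n_angular)
        diff = self.embed_geometries(g_ts) - self.embed_geometries(g_r)
        out = self.head(diff)
        return out.reshape(len(batch)) if self.n_outputs == 1 else out
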