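"""Independent brute-force oracles used by the unit and acceptance tests.

These re-derive quantities from their definitions with plain loops and dicts,
deliberately sharing no code path with the vectorized implementations they
check.
"""

from __future__ import annotations

import numpy as np


def dmpnn_edge_states_bruteforce(node_x: np.ndarray, edges: list[tuple[int, int]],
                                 edge_attr: np.ndarray, w_in: np.ndarray,
                                 b_in: np.ndarray, w_h: np.ndarray,
                                 depth: int) -> dict[tuple[int, int], np.ndarray]:
    """Directed-edge message recursion evaluated literally.

    ``edges`` lists directed edges (v, w) with attributes aligned; the state of
    (v, w) at step t+1 is relu(h0 + W_h @ sum of states of (u, v) with u != w).
    """
    def relu(x):
        return np.maximum(x, 0.0)

    h0 = {}
    for e, (v, w) in enumerate(edges):
        h0[(v, w)] = relu(np.concatenate([node_x[v], edge_attr[e]]) @ w_in + b_in)
    h = dict(h0)
    for _ in range(depth):
        nxt = {}
        for (v, w) in edges:
            incoming = sum((h[(u, vv)] for (u, vv) in edges if vv == v and u != w),
                           np.zeros(w_h.shape[1]))
            nxt[(v, w)] = relu(h0[(v, w)] + incoming @ w_h)
        h = nxt
    return h


def rwse_bruteforce(adjacency: np.ndarray, k: int) -> np.ndarray:
    """Return probabilities of k-step walk returns via explicit matrix powers."""
    deg = adjacency.sum(axis=1)
    p = np.zeros_like(adjacency, dtype=float)
    nz = deg > 0
    p[nz] = adjacency[nz] / deg[nz, None]
    out = np.zeros((adjacency.shape[0], k))
    for j in range(1, k + 1):
        out[:, j - 1] = np.diag(np.linalg.matrix_power(p, j))
    return out


def all_undirected_graphs(n: int):
    """Yield edge lists of every undirected simple graph on n labeled nodes."""
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    for mask in range(1 << len(pairs)):
        yield [pairs[b] for b in range(len(pairs)) if mask >> b & 1]
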