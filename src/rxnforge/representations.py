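"""Reaction representations: differential fingerprints, token sequences,
condensed graphs of reaction (CGR), and paired 3D geometries.

Each representation is a pure function of a parsed :class:`~rxnforge.core_data.Reaction`
(or of XYZ files for geometries) so that swapping the representation of a
pipeline is a configuration change, not a code change.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

from .core_data import BondOrder, Molecule, Reaction
from .errors import ConfigError, GeometryError, MappingError, ParseError, TokenizationError

# ---------------------------------------------------------------------------
# differential reaction fingerprint (DRFP)
# ---------------------------------------------------------------------------


@dataclass
class FingerprintVector:
    bits: np.ndarray  # uint8 vector of length n_bits
    n_bits: int
    radius: int

    def popcount(self) -> int:
        return int(self.bits.sum())


def _shingles(mols: Sequence[Molecule], radius: int) -> set:
    """Canonical SMILES of the circular environment of every heavy atom at
    radii 0..radius, over all molecules of one reaction side (maps stripped)."""
    out: set = set()
    for m in mols:
        rd = Chem.Mol(m.to_rdkit())
        for a in rd.GetAtoms():
            a.SetAtomMapNum(0)
        for atom in rd.GetAtoms():
            if atom.GetSymbol() == "H":
                continue
            for rad in range(radius + 1):
                if rad == 0:
                    smi = Chem.MolFragmentToSmiles(rd, atomsToUse=[atom.GetIdx()],
                                                   canonical=True)
                else:
                    env = Chem.FindAtomEnvironmentOfRadiusN(rd, rad, atom.GetIdx())
                    if not env:
                        break
                    atoms = set()
                    for bidx in env:
                        b = rd.GetBondWithIdx(bidx)
                        atoms.update((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
                    smi = Chem.MolFragmentToSmiles(rd, atomsToUse=sorted(atoms),
                                                   bondsToUse=list(env), canonical=True)
                out.add(smi)
    return out


def _stable_hash(s: str, seed: int) -> int:
    h = hashlib.blake2b(s.encode(), digest_size=8, salt=seed.to_bytes(8, "little"))
    return int.from_bytes(h.digest(), "little")


def drfp_fingerprint(r: Reaction, radius: int = 3, n_bits: int = 2048,
                     seed: int = 0) -> FingerprintVector:
    """Differential reaction fingerprint.

    The symmetric difference of the reactant-side and product-side circular
    substructure (shingle) sets is hashed into a bit vector, so substructures
    common to both sides cancel and only environments that appear or disappear
    across the reaction set bits.  Invariant to atom-map labels and to molecule
    order within each side; ``fp(A>>B) == fp(B>>A)``.
    """
    if n_bits <= 0 or (n_bits & (n_bits - 1)) != 0:
        raise ConfigError(f"n_bits must be a positive power of two, got {n_bits}")
    left = _shingles(r.reactants, radius)
    right = _shingles(r.products, radius)
    bits = np.zeros(n_bits, dtype=np.uint8)
    for shingle in left ^ right:
        bits[_stable_hash(shingle, seed) % n_bits] = 1
    return FingerprintVector(bits, n_bits, radius)


# ---------------------------------------------------------------------------
# SMILES tokenization
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|>>|Cl|Br|%\d{2}|[BCNOPSFI]|[bcnops]|[0-9]|\(|\)|\.|=|#|-|\+|/|\\|:|~|@@|@|\*|>|\$|[A-Za-z])"
)

UNK_TOKEN = "<unk>"
PAD_TOKEN = "<pad>"


@dataclass
class TokenSequence:
    tokens: list[str]
    molecule_boundaries: list[tuple[int, int]]  # [start, end) token ranges per molecule
    vocab_ids: Optional[list[int]] = None

    def __len__(self) -> int:
        return len(self.tokens)


def tokenize_smiles(s: str) -> TokenSequence:
    """Tokenize a molecule or reaction SMILES by the standard token grammar.

    Bracket atoms, two-letter elements, ``%nn`` ring closures, ``>>`` and all
    single-character symbols are single tokens; concatenating the tokens
    reproduces the input exactly.  Molecule boundaries are recorded at ``.``
    and ``>>`` (and single ``>``) separators.
    """
    tokens: list[str] = []
    pos = 0
    while pos < len(s):
        if s[pos] == "[":
            close = s.find("]", pos)
            if close < 0:
                raise TokenizationError(f"unclosed bracket at position {pos} in {s!r}")
        m = _TOKEN_RE.match(s, pos)
        if m is None:
            raise TokenizationError(f"unrecognized character {s[pos]!r} at position {pos} in {s!r}")
        tokens.append(m.group(0))
        pos = m.end()
    boundaries: list[tuple[int, int]] = []
    start = 0
    for i, tok in enumerate(tokens):
        if tok in (".", ">>", ">"):
            if i > start:
                boundaries.append((start, i))
            start = i + 1
    if len(tokens) > start:
        boundaries.append((start, len(tokens)))
    return TokenSequence(tokens, boundaries)


class Vocabulary:
    """Token-to-id mapping built from the training split only; unseen tokens
    map to a reserved UNK id (0), PAD is 1."""

    def __init__(self) -> None:
        self._ids = {UNK_TOKEN: 0, PAD_TOKEN: 1}

    @property
    def size(self) -> int:
        return len(self._ids)

    def fit(self, sequences: Sequence[TokenSequence]) -> "Vocabulary":
        for seq in sequences:
            for tok in seq.tokens:
                if tok not in self._ids:
                    self._ids[tok] = len(self._ids)
        return self

    def encode(self, seq: TokenSequence) -> TokenSequence:
        seq.vocab_ids = [self._ids.get(t, 0) for t in seq.tokens]
        return seq


# ---------------------------------------------------------------------------
# condensed graph of reaction (CGR)
# ---------------------------------------------------------------------------

ELEMENT_ALPHABET = ("H", "C", "N", "O", "F", "S", "Cl", "Br")  # + implicit "other"
_BOND_CATEGORIES: tuple = (None, 1, 2, 3, "aromatic")  # None = bond absent


@dataclass
class ReactionGraph:
    """CGR with one node per mapped heavy atom (ordered by map label) and the
    union of reactant/product bonds materialized as directed edge pairs."""

    node_features: np.ndarray          # (n, d_node) float
    edge_index: np.ndarray             # (2, E) int; edges 2k and 2k+1 are reverses
    edge_features: np.ndarray          # (E, d_edge) float
    labels: list[int] = field(default_factory=list)  # map label per node row

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[1]

    def reverse_index(self) -> np.ndarray:
        """Index of the reverse of each directed edge."""
        rev = np.arange(self.n_edges)
        rev[0::2] += 1
        rev[1::2] -= 1
        return rev

    def undirected_adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes))
        for k in range(0, self.n_edges, 2):
            i, j = self.edge_index[0, k], self.edge_index[1, k]
            a[i, j] = a[j, i] = 1.0
        return a


def _atom_state(r: Reaction, side: str) -> dict[int, dict]:
    """Per-map-label heavy-atom state on one reaction side."""
    mols = r.reactants if side == "reactants" else r.products
    state: dict[int, dict] = {}
    for mol in mols:
        rd = mol.to_rdkit()
        ring = rd.GetRingInfo()
        for i, (atom, m) in enumerate(zip(mol.atoms, mol.map_numbers)):
            if atom.element == "H":
                continue
            if m is None:
                raise MappingError(f"unmapped heavy atom in {r.identifier!r}")
            degree = sum(1 for b in mol.bonds if i in (b.i, b.j)
                         and mol.atoms[b.i].element != "H"
                         and mol.atoms[b.j].element != "H")
            state[m] = {"element": atom.element, "degree": degree,
                        "charge": atom.formal_charge, "aromatic": float(atom.aromatic),
                        "n_hs": atom.n_hs, "in_ring": float(ring.NumAtomRings(i) > 0)}
    return state


def _element_onehot(symbol: str) -> np.ndarray:
    v = np.zeros(len(ELEMENT_ALPHABET) + 1)
    if symbol in ELEMENT_ALPHABET:
        v[ELEMENT_ALPHABET.index(symbol)] = 1.0
    else:
        v[-1] = 1.0
    return v


def _order_onehot(order: Optional[BondOrder]) -> np.ndarray:
    v = np.zeros(len(_BOND_CATEGORIES))
    v[_BOND_CATEGORIES.index(order)] = 1.0
    return v


#: node feature layout: element one-hot (9) + reactant state (degree, charge,
#: aromatic, n_hs, in_ring) + product-minus-reactant differences of the same 5
CGR_NODE_DIM = len(ELEMENT_ALPHABET) + 1 + 10
#: edge layout: reactant-order one-hot + product-order one-hot + changed flag
CGR_EDGE_DIM = 2 * len(_BOND_CATEGORIES) + 1


def build_cgr(r: Reaction) -> ReactionGraph:
    """Build the condensed graph of reaction.

    Nodes are mapped heavy atoms in increasing map-label order.  Node features
    concatenate the reactant-state atom features with product-minus-reactant
    difference features; edge features concatenate one-hot reactant and product
    bond orders, where "absent" is its own category so that broken and formed
    bonds are visible to the model, plus a dynamic-bond flag marking edges
    whose order differs between the two sides.
    """
    r.check_conservation()
    rs = _atom_state(r, "reactants")
    ps = _atom_state(r, "products")
    if set(rs) != set(ps):
        raise MappingError(f"reaction {r.identifier!r} is not atom-conserving")
    labels = sorted(rs)
    row = {m: i for i, m in enumerate(labels)}
    nodes = np.zeros((len(labels), CGR_NODE_DIM))
    for m in labels:
        a, b = rs[m], ps[m]
        base = [a["degree"], a["charge"], a["aromatic"], a["n_hs"], a["in_ring"]]
        diff = [b["degree"] - a["degree"], b["charge"] - a["charge"],
                b["aromatic"] - a["aromatic"], b["n_hs"] - a["n_hs"],
                b["in_ring"] - a["in_ring"]]
        nodes[row[m]] = np.concatenate([_element_onehot(a["element"]), base, diff])

    rb = r.bond_labels("reactants")
    pb = r.bond_labels("products")
    src, dst, efeat = [], [], []
    for pair in sorted((tuple(sorted(p)) for p in set(rb) | set(pb))):
        i, j = row[pair[0]], row[pair[1]]
        ro, po = rb.get(frozenset(pair)), pb.get(frozenset(pair))
        feat = np.concatenate([_order_onehot(ro), _order_onehot(po),
                               [float(ro != po)]])
        src += [i, j]
        dst += [j, i]
        efeat += [feat, feat]
    edge_index = (np.array([src, dst], dtype=int) if src
                  else np.zeros((2, 0), dtype=int))
    edge_features = (np.array(efeat) if efeat else np.zeros((0, CGR_EDGE_DIM)))
    return ReactionGraph(nodes, edge_index, edge_features, labels)


def add_virtual_node(g: ReactionGraph) -> ReactionGraph:
    """Append a virtual node connected bidirectionally to all original nodes.

    Node features gain an ``is_virtual`` flag column and edge features an
    ``is_virtual_edge`` flag column; applying the transform twice adds two
    distinct virtual nodes (it is not idempotent).
    """
    n = g.n_nodes
    nodes = np.hstack([g.node_features, np.zeros((n, 1))])
    vrow = np.zeros((1, nodes.shape[1]))
    vrow[0, -1] = 1.0
    nodes = np.vstack([nodes, vrow])
    src = list(g.edge_index[0])
    dst = list(g.edge_index[1])
    efeat = np.hstack([g.edge_features, np.zeros((g.n_edges, 1))])
    new_rows = []
    for i in range(n):
        src += [n, i]
        dst += [i, n]
        row = np.zeros(efeat.shape[1])
        row[-1] = 1.0
        new_rows += [row, row]
    efeat = np.vstack([efeat] + [np.array(new_rows)]) if new_rows else efeat
    edge_index = np.array([src, dst], dtype=int) if src else np.zeros((2, 0), dtype=int)
    return ReactionGraph(nodes, edge_index, efeat, labels=list(g.labels) + [-1])


def rwse(g: ReactionGraph, k: int) -> np.ndarray:
    """Random-walk structural encoding: entry (i, j) is the probability that a
    degree-normalized random walk from node i returns to i in exactly j+1 steps
    (j = 0..k-1), on the undirected bond graph.  Isolated nodes get zeros."""
    if k < 1:
        raise ConfigError(f"rwse needs k >= 1, got {k}")
    a = g.undirected_adjacency()
    deg = a.sum(axis=1)
    p = np.divide(a, deg[:, None], out=np.zeros_like(a), where=deg[:, None] > 0)
    out = np.zeros((g.n_nodes, k))
    m = p.copy()
    for j in range(k):
        out[:, j] = np.diag(m)
        m = m @ p
    return out


def apply_transforms(g: ReactionGraph, transforms: Sequence[dict]) -> ReactionGraph:
    """Apply a chain of graph transforms described by config dicts."""
    for t in transforms:
        name = t.get("name")
        if name == "virtual_node":
            g = add_virtual_node(g)
        elif name == "rwse":
            enc = rwse(g, int(t.get("k", 8)))
            g = ReactionGraph(np.hstack([g.node_features, enc]), g.edge_index,
                              g.edge_features, g.labels)
        else:
            raise ConfigError(f"unknown transform {name!r}")
    return g


# ---------------------------------------------------------------------------
# 3D geometry pairs
# ---------------------------------------------------------------------------


@dataclass
class GeometryPair:
    """Reactant and transition-state coordinates over an identical atom list."""

    elements: list[str]
    r_coords: np.ndarray   # (n, 3) Angstrom
    ts_coords: np.ndarray  # (n, 3) Angstrom


def read_xyz(path: str) -> tuple[list[str], np.ndarray]:
    """Parse a standard XYZ file (count line, comment line, ``El x y z`` rows)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"empty XYZ file: {path}")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path}, line 1: expected an atom count") from exc
    if len(lines) < n + 2:
        raise ParseError(f"{path}: declares {n} atoms but has {len(lines)} lines")
    elements, coords = [], []
    for ln in range(2, 2 + n):
        parts = lines[ln].split()
        if len(parts) < 4:
            raise ParseError(f"{path}, line {ln + 1}: expected 'El x y z'")
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError as exc:
            raise ParseError(f"{path}, line {ln + 1}: bad coordinate") from exc
        elements.append(parts[0])
        coords.append(xyz)
    return elements, np.array(coords)


def load_geometry_pair(r_xyz: str, ts_xyz: str) -> GeometryPair:
    """Load reactant and TS XYZ files, enforcing identical atom lists."""
    r_el, r_xy = read_xyz(r_xyz)
    t_el, t_xy = read_xyz(ts_xyz)
    if len(r_el) != len(t_el):
        raise GeometryError(
            f"atom count mismatch: {r_xyz} has {len(r_el)}, {ts_xyz} has {len(t_el)}")
    if r_el != t_el:
        raise GeometryError(
            f"element order mismatch between {r_xyz} ({r_el}) and {ts_xyz} ({t_el})")
    return GeometryPair(r_el, r_xy, t_xy)
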