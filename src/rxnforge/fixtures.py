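"""Synthetic atom-mapped reaction datasets with a known target-generating model.

The generator emulates unimolecular organic reactions: a random connected
heavy-atom molecular graph with valence-legal bonds (C/N/O by default), a
small number of bond edits (break / form / order change) that keep both sides
valence-legal and atom-conserving, and a scalar target

    target = w_b * (number of changed bonds)
           + w_r * (number of core atoms that sit in a reactant ring)
           + Normal(0, sigma_eps)

so that every pipeline stage — parsing, splitting, representations, training —
can be exercised against ground truth with no download.  Optional toy 3D
geometries (force-layout reactant coordinates, TS = midpoint of reactant and
product layouts plus a small seeded jitter) exercise geometry I/O and the
TS - R difference head; they are *not* physical conformers and carry no
energetic meaning.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .core_data import DatasetTable, Reaction, parse_reaction_smiles
from .errors import GenerationError
from .representations import GeometryPair

VALENCE = {"C": 4, "N": 3, "O": 2}
_RD_ORDER = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}


@dataclass
class FixtureSpec:
    """Study conditions for one generated dataset."""

    n: int = 2000
    seed: int = 0
    heavy_atom_range: tuple[int, int] = (3, 8)
    elements: tuple[str, ...] = ("C", "N", "O")
    bond_change_range: tuple[int, int] = (1, 3)
    w_b: float = 5.0          # kcal/mol per changed bond
    w_r: float = 2.0          # kcal/mol per in-ring core atom
    sigma_eps: float = 1.0    # kcal/mol observation noise
    geometry: bool = False
    ring_prob: float = 0.4    # chance of closing one extra ring
    double_bond_prob: float = 0.3
    max_retries: int = 50

    def validate(self) -> None:
        lo, hi = self.heavy_atom_range
        if not (2 <= lo <= hi):
            raise GenerationError(f"invalid heavy-atom range {self.heavy_atom_range}")
        klo, khi = self.bond_change_range
        if not (0 <= klo <= khi):
            raise GenerationError(f"invalid bond-change range {self.bond_change_range}")
        if self.sigma_eps < 0:
            raise GenerationError("sigma_eps must be >= 0")
        for e in self.elements:
            if e not in VALENCE:
                raise GenerationError(f"element {e!r} has no configured valence")


def _spare(element: str, bonds: dict, atom: int) -> int:
    used = sum(o for (i, j), o in bonds.items() if atom in (i, j))
    return VALENCE[element] - used


def _random_molecule(rng: np.random.Generator, spec: FixtureSpec):
    """Random connected valence-legal heavy-atom graph: elements and bond orders."""
    lo, hi = spec.heavy_atom_range
    m = int(rng.integers(lo, hi + 1))
    elements = [str(rng.choice(spec.elements)) for _ in range(m)]
    bonds: dict[tuple[int, int], int] = {}
    for i in range(1, m):
        anchors = [j for j in range(i) if _spare(elements[j], bonds, j) >= 1]
        if not anchors:
            return None
        j = int(rng.choice(anchors))
        bonds[(min(i, j), max(i, j))] = 1
    if rng.random() < spec.ring_prob and m >= 3:
        open_pairs = [(i, j) for i in range(m) for j in range(i + 1, m)
                      if (i, j) not in bonds
                      and _spare(elements[i], bonds, i) >= 1
                      and _spare(elements[j], bonds, j) >= 1]
        if open_pairs:
            i, j = open_pairs[int(rng.integers(len(open_pairs)))]
            bonds[(i, j)] = 1
    if rng.random() < spec.double_bond_prob:
        upgradable = [p for p, o in bonds.items()
                      if _spare(elements[p[0]], bonds, p[0]) >= 1
                      and _spare(elements[p[1]], bonds, p[1]) >= 1]
        if upgradable:
            p = upgradable[int(rng.integers(len(upgradable)))]
            bonds[p] = 2
    return elements, bonds


def _sample_edits(rng: np.random.Generator, elements: list[str],
                  r_bonds: dict, k: int):
    """Sample k bond edits, each touching a distinct atom pair, keeping the
    product side valence-legal.  Returns the product bond dict or None."""
    p_bonds = dict(r_bonds)
    edited: set = set()
    m = len(elements)
    for _ in range(k):
        candidates = []
        for pair, order in p_bonds.items():
            if pair in edited:
                continue
            candidates.append(("break", pair))
            if order >= 2:
                candidates.append(("down", pair))
            if order < 3 and _spare(elements[pair[0]], p_bonds, pair[0]) >= 1 \
                    and _spare(elements[pair[1]], p_bonds, pair[1]) >= 1:
                candidates.append(("up", pair))
        for i in range(m):
            for j in range(i + 1, m):
                if (i, j) in p_bonds or (i, j) in edited:
                    continue
                if _spare(elements[i], p_bonds, i) >= 1 \
                        and _spare(elements[j], p_bonds, j) >= 1:
                    candidates.append(("form", (i, j)))
        if not candidates:
            return None
        action, pair = candidates[int(rng.integers(len(candidates)))]
        if action == "break":
            del p_bonds[pair]
        elif action == "down":
            p_bonds[pair] -= 1
        elif action == "up":
            p_bonds[pair] += 1
        else:
            p_bonds[pair] = 1
        if p_bonds.get(pair) == r_bonds.get(pair):
            return None  # edit cancelled out; resample record
        edited.add(pair)
    return p_bonds, edited


def _to_smiles(elements: list[str], bonds: dict, labels: list[int]) -> str:
    em = Chem.RWMol()
    for el, lab in zip(elements, labels):
        a = Chem.Atom(el)
        a.SetAtomMapNum(lab)
        em.AddAtom(a)
    for (i, j), order in bonds.items():
        em.AddBond(i, j, _RD_ORDER[order])
    mol = em.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def _ring_atoms(elements: list[str], bonds: dict) -> set:
    em = Chem.RWMol()
    for el in elements:
        em.AddAtom(Chem.Atom(el))
    for (i, j), order in bonds.items():
        em.AddBond(i, j, _RD_ORDER[order])
    mol = em.GetMol()
    Chem.SanitizeMol(mol)
    ring = mol.GetRingInfo()
    return {i for i in range(len(elements)) if ring.NumAtomRings(i) > 0}


def _layout(elements: list[str], bonds: dict, rng: np.random.Generator,
            init: np.ndarray = None, n_steps: int = 200) -> np.ndarray:
    """Deterministic force layout: springs toward 1.5 A on bonds, soft
    repulsion between all pairs.  Distance-geometry flavored, not physical."""
    n = len(elements)
    x = rng.normal(0.0, 1.5, size=(n, 3)) if init is None else init.copy()
    pairs = list(bonds)
    for _ in range(n_steps):
        grad = np.zeros_like(x)
        for i, j in pairs:
            d = x[i] - x[j]
            r = max(np.linalg.norm(d), 1e-6)
            f = (r - 1.5) * d / r
            grad[i] += f
            grad[j] -= f
        diff = x[None, :, :] - x[:, None, :]
        dist = np.maximum(np.linalg.norm(diff, axis=-1), 0.3)
        rep = diff / dist[..., None] ** 3
        grad += 0.5 * rep.sum(axis=1)
        x -= 0.1 * grad
    return x - x.mean(axis=0)


def generate_dataset(spec: FixtureSpec) -> tuple[DatasetTable, dict[str, GeometryPair]]:
    """Generate ``spec.n`` atom-mapped reactions (and toy geometries when
    ``spec.geometry``).  Deterministic for a fixed spec and seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records: list[Reaction] = []
    geoms: dict[str, GeometryPair] = {}
    for idx in range(spec.n):
        rec = None
        for _ in range(spec.max_retries):
            mol = _random_molecule(rng, spec)
            if mol is None:
                continue
            elements, r_bonds = mol
            klo, khi = spec.bond_change_range
            k = int(rng.integers(klo, khi + 1))
            res = _sample_edits(rng, elements, r_bonds, k)
            if res is None:
                continue
            p_bonds, edited = res
            labels = [int(l) + 1 for l in rng.permutation(len(elements))]
            try:
                r_smi = _to_smiles(elements, r_bonds, labels)
                p_smi = _to_smiles(elements, p_bonds, labels)
            except Exception:
                continue
            ident = f"rxn{idx:05d}"
            candidate = parse_reaction_smiles(f"{r_smi}>>{p_smi}", identifier=ident)
            # aromatic re-perception can rewrite bond orders; keep only records
            # whose parsed bond sets match the sampled edit exactly, so the
            # target-generating model holds for the record as parsed
            lab = {i: l for i, l in enumerate(labels)}
            want_r = {frozenset((lab[i], lab[j])): o for (i, j), o in r_bonds.items()}
            want_p = {frozenset((lab[i], lab[j])): o for (i, j), o in p_bonds.items()}
            if candidate.bond_labels("reactants") != want_r \
                    or candidate.bond_labels("products") != want_p:
                continue
            core_atoms = {a for pair in edited for a in pair}
            ring = _ring_atoms(elements, r_bonds)
            n_ring_core = len(core_atoms & ring)
            target = spec.w_b * k + spec.w_r * n_ring_core
            if spec.sigma_eps > 0:
                target += rng.normal(0.0, spec.sigma_eps)
            rec = candidate
            rec.target = float(target)
            if spec.geometry:
                r_xyz = _layout(elements, r_bonds, rng)
                p_xyz = _layout(elements, p_bonds, rng, init=r_xyz, n_steps=100)
                ts = 0.5 * (r_xyz + p_xyz) + rng.normal(0.0, 0.05, size=r_xyz.shape)
                order = np.argsort(labels)  # atom rows in map-label order
                geoms[ident] = GeometryPair([elements[i] for i in order],
                                            r_xyz[order], ts[order])
            break
        if rec is None:
            raise GenerationError(
                f"could not generate record {idx} within {spec.max_retries} retries; "
                f"spec may be infeasible: {spec}")
        records.append(rec)
    return DatasetTable(records, source_path=f"<fixture seed={spec.seed}>"), geoms


def write_dataset(table: DatasetTable, geoms: dict[str, GeometryPair],
                  out_dir: str) -> str:
    """Write ``reactions.csv`` (+ ``geoms/<id>_{r,ts}.xyz``) under ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    csv_path = os.path.join(out_dir, "reactions.csv")
    with open(csv_path, "w") as fh:
        fh.write("id,rxn_smiles,target\n")
        for rec in table.records:
            fh.write(f"{rec.identifier},{rec.to_smiles()},{rec.target:.6f}\n")
    if geoms:
        gdir = os.path.join(out_dir, "geoms")
        os.makedirs(gdir, exist_ok=True)
        for ident, pair in geoms.items():
            for tag, coords in (("r", pair.r_coords), ("ts", pair.ts_coords)):
                with open(os.path.join(gdir, f"{ident}_{tag}.xyz"), "w") as fh:
                    fh.write(f"{len(pair.elements)}\n{ident} {tag}\n")
                    for el, (x, y, z) in zip(pair.elements, coords):
                        fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")
    return csv_path
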