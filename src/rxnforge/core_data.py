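"""Reaction records and tabular ingestion.

Atom-mapped reaction SMILES are parsed into light-weight :class:`Molecule` /
:class:`Reaction` records that every downstream component (splitters,
representations, models) consumes.  RDKit does the actual SMILES perception;
this module owns the atom-map bookkeeping and the atom-conservation contract.

Conventions
-----------
* internal atom indices are 0-based; atom-map labels are the 1-based integers
  written in the SMILES
* hydrogens are implicit: heavy-atom graphs feed the representations, and the
  total hydrogen count of each heavy atom is stored as an atom attribute
* the middle (agents) field of a three-part reaction SMILES is parsed and
  discarded with a warning, since no in-scope modality consumes it
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .errors import DatasetError, MappingError, ParseError

RDLogger.DisableLog("rdApp.*")

#: bond order vocabulary: integers for single/double/triple, "aromatic" as its
#: own category (kept categorical rather than order 1.5)
BondOrder = Union[int, str]

_RD_ORDER = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: "aromatic",
}
_ORDER_RD = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
             3: Chem.BondType.TRIPLE, "aromatic": Chem.BondType.AROMATIC}


@dataclass
class Atom:
    element: str
    formal_charge: int = 0
    n_hs: int = 0
    aromatic: bool = False


@dataclass
class Bond:
    i: int
    j: int
    order: BondOrder


@dataclass
class Molecule:
    """A single connected (or multi-fragment) molecule with optional maps/coords."""

    atoms: list[Atom]
    bonds: list[Bond]
    map_numbers: list[Optional[int]] = field(default_factory=list)
    coords: Optional[np.ndarray] = None  # (n_atoms, 3), Angstrom

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if not self.map_numbers:
            self.map_numbers = [None] * n
        seen = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n) or b.i == b.j:
                raise ParseError(f"bond ({b.i},{b.j}) has invalid endpoints for {n} atoms")
            key = frozenset((b.i, b.j))
            if key in seen:
                raise ParseError(f"duplicate bond between atoms {b.i} and {b.j}")
            seen.add(key)
        present = [m for m in self.map_numbers if m is not None]
        if len(present) != len(set(present)):
            dupes = [m for m, c in Counter(present).items() if c > 1]
            raise MappingError(f"duplicate atom-map labels within one molecule: {dupes}")

    @property
    def n_heavy(self) -> int:
        return sum(1 for a in self.atoms if a.element != "H")

    def to_rdkit(self) -> Chem.Mol:
        em = Chem.RWMol()
        for a, m in zip(self.atoms, self.map_numbers):
            ra = Chem.Atom(a.element)
            ra.SetFormalCharge(a.formal_charge)
            ra.SetIsAromatic(a.aromatic)
            if a.element != "H":
                ra.SetNumExplicitHs(a.n_hs)
                ra.SetNoImplicit(True)
            if m is not None:
                ra.SetAtomMapNum(m)
            em.AddAtom(ra)
        for b in self.bonds:
            em.AddBond(b.i, b.j, _ORDER_RD[b.order])
        mol = em.GetMol()
        Chem.SanitizeMol(mol)
        return mol

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol) -> "Molecule":
        atoms, maps = [], []
        for a in mol.GetAtoms():
            atoms.append(Atom(a.GetSymbol(), a.GetFormalCharge(),
                              a.GetTotalNumHs(), a.GetIsAromatic()))
            maps.append(a.GetAtomMapNum() or None)
        bonds = [Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _RD_ORDER[b.GetBondType()])
                 for b in mol.GetBonds()]
        coords = None
        if mol.GetNumConformers():
            coords = np.asarray(mol.GetConformer().GetPositions(), dtype=float)
        return cls(atoms, bonds, maps, coords)

    def to_smiles(self) -> str:
        return Chem.MolToSmiles(self.to_rdkit())


@dataclass
class Reaction:
    """One atom-mapped reaction with an optional scalar target (kcal/mol or class)."""

    reactants: list[Molecule]
    products: list[Molecule]
    target: Optional[float] = None
    identifier: str = ""

    @property
    def is_mapped(self) -> bool:
        for side in (self.reactants, self.products):
            for mol in side:
                for atom, m in zip(mol.atoms, mol.map_numbers):
                    if atom.element != "H" and m is None:
                        return False
        return True

    def heavy_label_multiset(self, side: str) -> Counter:
        mols = self.reactants if side == "reactants" else self.products
        c: Counter = Counter()
        for mol in mols:
            for atom, m in zip(mol.atoms, mol.map_numbers):
                if atom.element != "H" and m is not None:
                    c[m] += 1
        return c

    def check_conservation(self) -> None:
        """Raise :class:`MappingError` unless reactant/product heavy-atom map
        label multisets agree (when the reaction is fully mapped)."""
        if not self.is_mapped:
            return
        r, p = self.heavy_label_multiset("reactants"), self.heavy_label_multiset("products")
        if r != p:
            lost = sorted((r - p).elements())
            gained = sorted((p - r).elements())
            raise MappingError(
                f"atom-map labels not conserved in '{self.identifier}': "
                f"lost from products {lost}, unexplained in products {gained}")

    def bond_labels(self, side: str) -> dict[frozenset, BondOrder]:
        """Heavy-atom bonds of one side keyed by map-label pair."""
        mols = self.reactants if side == "reactants" else self.products
        out: dict[frozenset, BondOrder] = {}
        for mol in mols:
            for b in mol.bonds:
                ai, aj = mol.atoms[b.i], mol.atoms[b.j]
                mi, mj = mol.map_numbers[b.i], mol.map_numbers[b.j]
                if ai.element == "H" or aj.element == "H":
                    continue
                if mi is None or mj is None:
                    raise MappingError(
                        f"unmapped heavy atom on a bond in '{self.identifier}'")
                out[frozenset((mi, mj))] = b.order
        return out

    def to_smiles(self) -> str:
        r = ".".join(m.to_smiles() for m in self.reactants)
        p = ".".join(m.to_smiles() for m in self.products)
        return f"{r}>>{p}"


@dataclass
class DatasetTable:
    """Ordered reaction records; row order equals file row order."""

    records: list[Reaction]
    source_path: str = ""
    column_map: dict = field(default_factory=lambda: dict(DEFAULT_COLUMNS))

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i: int) -> Reaction:
        return self.records[i]

    def targets(self) -> np.ndarray:
        return np.array([r.target for r in self.records], dtype=float)


DEFAULT_COLUMNS = {"rxn_smiles": "rxn_smiles", "target": "target"}


def _parse_side(smiles: str, what: str) -> list[Molecule]:
    if smiles == "":
        return []
    mol = Chem.MolFromSmiles(smiles, sanitize=True)
    if mol is None:
        raise ParseError(f"could not parse {what} fragment {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    return [Molecule.from_rdkit(f) for f in frags]


def parse_reaction_smiles(rxn: str, identifier: str = "",
                          target: Optional[float] = None) -> Reaction:
    """Parse an atom-mapped reaction SMILES ``reactants>agents>products``.

    Agents are discarded with a warning.  When every heavy atom carries a map
    label, atom conservation (equal label multisets on both sides) is enforced.
    """
    parts = rxn.split(">")
    if len(parts) != 3:
        raise ParseError(
            f"reaction SMILES must contain '>>' or '>agents>': {rxn!r}")
    r_smi, agents, p_smi = parts
    if agents:
        warnings.warn(f"discarding agents field {agents!r} of reaction {identifier or rxn!r}")
    reactants = _parse_side(r_smi, "reactant")
    products = _parse_side(p_smi, "product")
    reaction = Reaction(reactants, products, target=target, identifier=identifier or rxn)
    reaction.check_conservation()
    return reaction


def heavy_atom_count(r: Reaction) -> int:
    """Number of non-hydrogen atoms over all reactant molecules."""
    return sum(m.n_heavy for m in r.reactants)


def load_dataset(path: str, column_map: Optional[dict] = None,
                 skip_invalid: bool = False) -> DatasetTable:
    """Load a CSV of reaction SMILES and scalar targets into a :class:`DatasetTable`.

    Row order is preserved.  Rows that fail to parse (or have a blank target)
    abort the load with their row number unless ``skip_invalid`` is set, in
    which case they are dropped and reported via :mod:`warnings`.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DatasetError(f"empty dataset file: {path}") from exc
    for key in ("rxn_smiles", "target"):
        if cols[key] not in df.columns:
            raise DatasetError(
                f"missing column {cols[key]!r} in {path} (available: {list(df.columns)})")
    if len(df) == 0:
        raise DatasetError(f"dataset has a header but no rows: {path}")

    records: list[Reaction] = []
    skipped: list[tuple[int, str]] = []
    for row_no, row in enumerate(df.itertuples(index=False)):
        smi = getattr(row, cols["rxn_smiles"])
        tgt = getattr(row, cols["target"])
        try:
            if pd.isna(tgt):
                raise DatasetError(f"blank target in row {row_no} of {path}")
            rec = parse_reaction_smiles(str(smi), identifier=f"row{row_no}",
                                        target=float(tgt))
        except (ParseError, MappingError, DatasetError, ValueError) as exc:
            if skip_invalid:
                skipped.append((row_no, str(exc)))
                continue
            raise DatasetError(f"row {row_no} of {path}: {exc}") from exc
        records.append(rec)
    if skipped:
        warnings.warn(f"skipped {len(skipped)} invalid rows of {path}: "
                      + "; ".join(f"row {i}: {m}" for i, m in skipped[:10]))
    return DatasetTable(records, source_path=str(path), column_map=cols)
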