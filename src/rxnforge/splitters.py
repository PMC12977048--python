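"""In- and out-of-distribution data splitters.

Seven strategies are exposed: ``random``, ``size_asc``/``size_desc`` (records
ordered by reactant heavy-atom count), ``target_asc``/``target_desc`` (ordered
by the regression target), ``core`` (grouped by reaction core — the minimal
joint subgraph where bonds are broken, formed or change order) and
``scaffold`` (grouped by the Bemis–Murcko scaffold of the largest reactant
fragment).  Every splitter returns a :class:`SplitIndices` partition that is
disjoint, exhaustive and ratio-consistent, and can be saved/loaded as JSON for
reproducible evaluation.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .core_data import BondOrder, DatasetTable, Reaction, heavy_atom_count
from .errors import ConfigError, MappingError, RxnForgeError

STRATEGIES = ("random", "size_asc", "size_desc", "target_asc", "target_desc",
              "core", "scaffold")


@dataclass
class SplitIndices:
    """Disjoint train/val/test record indices with provenance."""

    train: list[int]
    val: list[int]
    test: list[int]
    strategy: str = ""
    seed: Optional[int] = None
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)

    def validate(self, n: Optional[int] = None) -> None:
        parts = [set(self.train), set(self.val), set(self.test)]
        total = len(self.train) + len(self.val) + len(self.test)
        union = parts[0] | parts[1] | parts[2]
        if len(union) != total:
            raise RxnForgeError("split partitions overlap")
        if n is not None and union != set(range(n)):
            raise RxnForgeError(
                f"split does not cover exactly 0..{n - 1} (got {len(union)} indices)")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SplitIndices):
            return NotImplemented
        return (self.train == other.train and self.val == other.val
                and self.test == other.test and self.strategy == other.strategy
                and self.seed == other.seed
                and tuple(self.ratios) == tuple(other.ratios))


@dataclass(frozen=True)
class ReactionCore:
    """Bonds broken/formed (order changes count as both) and the atoms they touch."""

    core_atoms: frozenset
    broken: frozenset  # of (label_pair, reactant_order, product_order)
    formed: frozenset
    canonical_key: str

    @property
    def n_changed_bonds(self) -> int:
        pairs = {b[0] for b in self.broken} | {f[0] for f in self.formed}
        return len(pairs)


def _check_ratios(ratios: Sequence[float]) -> tuple[float, float, float]:
    if len(ratios) != 3 or any(r < 0 for r in ratios):
        raise ConfigError(f"ratios must be three nonnegative reals, got {ratios}")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ConfigError(f"ratios must sum to 1, got {ratios} (sum {sum(ratios)})")
    return tuple(float(r) for r in ratios)  # type: ignore[return-value]


def _sizes(n: int, ratios: Sequence[float]) -> tuple[int, int, int]:
    n_train = round(n * ratios[0])
    n_val = round(n * ratios[1])
    return n_train, n_val, n - n_train - n_val


def _partition(order: Sequence[int], n: int, ratios, strategy, seed) -> SplitIndices:
    n_train, n_val, n_test = _sizes(n, ratios)
    if min(n_train, n_test) < 1:
        warnings.warn(f"{strategy} split on n={n}: a terminal partition is empty")
    if n_val == 0:
        warnings.warn(f"{strategy} split on n={n}: validation partition is empty")
    order = list(order)
    split = SplitIndices(order[:n_train], order[n_train:n_train + n_val],
                         order[n_train + n_val:], strategy=strategy, seed=seed,
                         ratios=tuple(ratios))
    split.validate(n)
    return split


def split_random(n: int, ratios: Sequence[float] = (0.8, 0.1, 0.1),
                 seed: int = 0) -> SplitIndices:
    """Uniform seeded shuffle of ``0..n-1``, partitioned contiguously."""
    ratios = _check_ratios(ratios)
    if n < 3:
        raise ConfigError(f"need at least 3 records to split, got {n}")
    order = np.random.default_rng(seed).permutation(n).tolist()
    return _partition(order, n, ratios, "random", seed)


def split_ordered(keys: Sequence[float], direction: str = "ascending",
                  ratios: Sequence[float] = (0.8, 0.1, 0.1)) -> SplitIndices:
    """Sort records by key (original index breaks ties), then cut contiguous blocks.

    Ascending puts the largest keys in the test set (extrapolation upward);
    descending puts the smallest there.
    """
    ratios = _check_ratios(ratios)
    if direction not in ("ascending", "descending"):
        raise ConfigError(f"direction must be ascending|descending, got {direction!r}")
    keys = list(keys)
    for i, k in enumerate(keys):
        if k is None or (isinstance(k, float) and np.isnan(k)):
            raise RxnForgeError(f"record {i} has no ordering key")
    sign = 1.0 if direction == "ascending" else -1.0
    order = sorted(range(len(keys)), key=lambda i: (sign * keys[i], i))
    name = "ordered_" + ("asc" if direction == "ascending" else "desc")
    return _partition(order, len(keys), ratios, name, None)


def split_grouped(group_keys: Sequence[str], ratios: Sequence[float] = (0.8, 0.1, 0.1),
                  seed: int = 0, strategy: str = "grouped") -> SplitIndices:
    """Shuffle groups and assign them whole: train fills to its quota first,
    then val, remainder to test.  No group key ever spans two partitions."""
    ratios = _check_ratios(ratios)
    n = len(group_keys)
    groups: dict[str, list[int]] = {}
    for i, k in enumerate(group_keys):
        groups.setdefault(k, []).append(i)
    if len(groups) < 3:
        raise ConfigError(
            f"grouped split needs >= 3 distinct groups, got {len(groups)}")
    names = sorted(groups)
    rng = np.random.default_rng(seed)
    order = [names[i] for i in rng.permutation(len(names))]
    n_train, n_val, _ = _sizes(n, ratios)
    train: list[int] = []
    val: list[int] = []
    test: list[int] = []
    for name in order:
        members = groups[name]
        if len(train) < n_train:
            train.extend(members)
        elif len(train) + len(val) < n_train + n_val:
            val.extend(members)
        else:
            test.extend(members)
    split = SplitIndices(train, val, test, strategy=strategy, seed=seed,
                         ratios=tuple(ratios))
    split.validate(n)
    return split


def _strip_maps(mol: Chem.Mol) -> Chem.Mol:
    mol = Chem.Mol(mol)
    for a in mol.GetAtoms():
        a.SetAtomMapNum(0)
    return mol


def _side_core_smiles(reaction: Reaction, side: str, core: frozenset) -> str:
    """Canonical SMILES of the subgraph induced by the core labels on one side."""
    frags = []
    mols = reaction.reactants if side == "reactants" else reaction.products
    for mol in mols:
        idx = [i for i, m in enumerate(mol.map_numbers)
               if m in core and mol.atoms[i].element != "H"]
        if not idx:
            continue
        rd = _strip_maps(mol.to_rdkit())
        bonds = [b.GetIdx() for b in rd.GetBonds()
                 if b.GetBeginAtomIdx() in set(idx) and b.GetEndAtomIdx() in set(idx)]
        frags.append(Chem.MolFragmentToSmiles(rd, atomsToUse=idx,
                                              bondsToUse=bonds or None,
                                              canonical=True))
    return ".".join(sorted(frags))


def reaction_core(r: Reaction) -> ReactionCore:
    """Extract the reaction core of a fully mapped, atom-conserving reaction.

    A bond counts as broken if its label pair exists in the reactants but is
    absent (or has a different order) in the products, and as formed in the
    converse case; an order change therefore contributes one broken and one
    formed entry.  The canonical key is label-permutation invariant.
    """
    if not r.is_mapped:
        raise MappingError(f"reaction {r.identifier!r} has unmapped heavy atoms")
    r.check_conservation()
    rb = r.bond_labels("reactants")
    pb = r.bond_labels("products")
    broken: set = set()
    formed: set = set()
    for pair in set(rb) | set(pb):
        ro: Optional[BondOrder] = rb.get(pair)
        po: Optional[BondOrder] = pb.get(pair)
        if ro == po:
            continue
        key = tuple(sorted(pair))
        if ro is not None:
            broken.add((key, ro, po))
        if po is not None:
            formed.add((key, ro, po))
    core = frozenset(l for b in broken | formed for l in b[0])
    if core:
        key = _side_core_smiles(r, "reactants", core) + ">>" + \
            _side_core_smiles(r, "products", core)
    else:
        key = ">>"
    return ReactionCore(core, frozenset(broken), frozenset(formed), key)


def reactant_scaffold(r: Reaction) -> str:
    """Bemis–Murcko scaffold (canonical SMILES) of the largest reactant fragment.

    Acyclic molecules have no ring system and map to the empty scaffold ``""``;
    ties on fragment size break by canonical-SMILES order.
    """
    best = None
    for mol in r.reactants:
        if mol.n_heavy == 0:
            continue
        smi = Chem.MolToSmiles(_strip_maps(mol.to_rdkit()))
        key = (mol.n_heavy, smi)
        if best is None or key[0] > best[0] or (key[0] == best[0] and key[1] < best[1]):
            best = key
    if best is None:
        return ""
    scaffold = MurckoScaffold.MurckoScaffoldSmiles(smiles=best[1])
    return scaffold


def split_dataset(table: DatasetTable, strategy: str,
                  ratios: Sequence[float] = (0.8, 0.1, 0.1),
                  seed: int = 0) -> SplitIndices:
    """Dispatch a named strategy on a dataset."""
    if strategy == "random":
        return split_random(len(table), ratios, seed)
    if strategy in ("size_asc", "size_desc"):
        keys = [heavy_atom_count(rec) for rec in table.records]
        direction = "ascending" if strategy == "size_asc" else "descending"
        s = split_ordered(keys, direction, ratios)
        s.strategy = strategy
        return s
    if strategy in ("target_asc", "target_desc"):
        keys = [rec.target for rec in table.records]
        direction = "ascending" if strategy == "target_asc" else "descending"
        s = split_ordered(keys, direction, ratios)
        s.strategy = strategy
        return s
    if strategy == "core":
        keys = [reaction_core(rec).canonical_key for rec in table.records]
        return split_grouped(keys, ratios, seed, strategy="core")
    if strategy == "scaffold":
        keys = [reactant_scaffold(rec) for rec in table.records]
        return split_grouped(keys, ratios, seed, strategy="scaffold")
    raise ConfigError(f"unknown split strategy {strategy!r}; choose from {STRATEGIES}")


def save_split(split: SplitIndices, path: str) -> None:
    with open(path, "w") as fh:
        json.dump({"strategy": split.strategy, "seed": split.seed,
                   "ratios": list(split.ratios), "train": list(split.train),
                   "val": list(split.val), "test": list(split.test)}, fh)


def load_split(path: str, n: Optional[int] = None) -> SplitIndices:
    """Load a split file; with ``n`` given, validate coverage of ``0..n-1``."""
    with open(path) as fh:
        d = json.load(fh)
    split = SplitIndices([int(i) for i in d["train"]], [int(i) for i in d["val"]],
                         [int(i) for i in d["test"]], strategy=d.get("strategy", ""),
                         seed=d.get("seed"), ratios=tuple(d.get("ratios", (0.8, 0.1, 0.1))))
    split.validate(n)
    return split


def export_split_csv(split: SplitIndices, path: str) -> None:
    """CSV export (index, partition) for interoperability."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "partition"])
        for name, idx in (("train", split.train), ("val", split.val), ("test", split.test)):
            for i in idx:
                writer.writerow([i, name])
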