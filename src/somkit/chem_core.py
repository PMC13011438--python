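"""Molecule perception, SYBYL-style atom typing, and topological distances.

The heavy-atom graph is the universe of every downstream computation:
hydrogens are folded into implicit counts during perception and never
appear as graph nodes.  Atom indices are 0-based and preserve the input
heavy-atom order (user-facing files use 1-based indices by SDF convention).

Aromaticity is perceived once, with RDKit's default model, and that single
model is applied to both training and prediction inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem, RDLogger

log = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.warning")

#: Sentinel distance for atoms in different fragments.
UNREACHABLE: int = np.iinfo(np.int32).max


class SomkitError(Exception):
    """Base class for all package errors."""


class PerceptionError(SomkitError):
    """Structure could not be parsed, sanitized, or typed."""


class Hybridization(str, Enum):
    SP = "sp"
    SP2 = "sp2"
    SP3 = "sp3"
    OTHER = "other"


# Default 26-entry SYBYL-style type table: common organic elements across
# hybridization states, plus a catch-all "Any".  The table is configurable
# (`SybylTypeTable.from_codes` / `from_file`) so an alternative table can be
# substituted without touching the encoding.
DEFAULT_SYBYL_CODES: tuple[str, ...] = (
    "C.1", "C.2", "C.3", "C.ar", "C.cat",
    "N.1", "N.2", "N.3", "N.4", "N.ar", "N.am", "N.pl3",
    "O.2", "O.3", "O.co2",
    "S.2", "S.3", "S.O", "S.O2",
    "P.3",
    "F", "Cl", "Br", "I",
    "Si.3",
    "Any",
)


@dataclass(frozen=True)
class SybylType:
    """A categorical atom type: element + hybridization/functional context."""

    code: str
    ordinal: int


class SybylTypeTable:
    """Ordered, bijective code <-> ordinal mapping; stable across runs."""

    def __init__(self, codes: Sequence[str]):
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate SYBYL type codes in table")
        self.codes: tuple[str, ...] = tuple(codes)
        self._ordinals = {c: i for i, c in enumerate(self.codes)}

    @classmethod
    def default(cls) -> "SybylTypeTable":
        return cls(DEFAULT_SYBYL_CODES)

    @classmethod
    def from_file(cls, path: str) -> "SybylTypeTable":
        """Load a table from a text file, one type code per line."""
        with open(path, "r", encoding="utf-8") as fh:
            codes = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
        return cls(codes)

    @property
    def size(self) -> int:
        return len(self.codes)

    def __contains__(self, code: str) -> bool:
        return code in self._ordinals

    def get(self, code: str) -> SybylType:
        try:
            return SybylType(code, self._ordinals[code])
        except KeyError:
            raise KeyError(f"SYBYL type {code!r} not in table {self.codes}")

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SybylTypeTable) and self.codes == other.codes


@dataclass
class AtomRecord:
    element: str
    implicit_h_count: int
    formal_charge: int
    aromatic: bool
    hybridization: Hybridization
    sybyl_type: Optional[SybylType] = None


@dataclass(frozen=True)
class BondRecord:
    """One bond, stored once; `order` is the Kekulé integer bond order."""

    i: int
    j: int
    order: int
    aromatic: bool


@dataclass
class MoleculeRecord:
    mol_id: str
    atoms: list[AtomRecord]
    bonds: list[BondRecord]
    som_labels: Optional[frozenset[int]] = None
    rdmol: Optional[Chem.Mol] = field(default=None, repr=False, compare=False)
    _adj: Optional[list[list[tuple[int, int, bool]]]] = field(
        default=None, repr=False, compare=False
    )
    _dist: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> list[tuple[int, int, bool]]:
        """(neighbor index, Kekulé order, aromatic flag) for heavy neighbors."""
        if self._adj is None:
            adj: list[list[tuple[int, int, bool]]] = [[] for _ in self.atoms]
            for b in self.bonds:
                adj[b.i].append((b.j, b.order, b.aromatic))
                adj[b.j].append((b.i, b.order, b.aromatic))
            self._adj = adj
        return self._adj[i]

    def distances(self) -> np.ndarray:
        if self._dist is None:
            self._dist = topological_distances(self)
        return self._dist


def _hybridization_of(atom: Chem.Atom) -> Hybridization:
    h = atom.GetHybridization()
    if h == Chem.HybridizationType.SP:
        return Hybridization.SP
    if h == Chem.HybridizationType.SP2:
        return Hybridization.SP2
    if h == Chem.HybridizationType.SP3:
        return Hybridization.SP3
    return Hybridization.OTHER


def _largest_fragment(mol: Chem.Mol, mol_id: str) -> tuple[Chem.Mol, dict[int, int]]:
    """Keep the largest connected fragment; return (mol, old->new index map)."""
    frags = Chem.GetMolFrags(mol)
    if len(frags) == 1:
        return mol, {i: i for i in range(mol.GetNumAtoms())}
    keep = max(frags, key=lambda f: (len(f), -min(f)))
    log.info(
        "molecule %s: %d fragments, keeping largest (%d of %d atoms)",
        mol_id, len(frags), len(keep), mol.GetNumAtoms(),
    )
    rw = Chem.RWMol(mol)
    for idx in sorted(set(range(mol.GetNumAtoms())) - set(keep), reverse=True):
        rw.RemoveAtom(idx)
    sub = rw.GetMol()
    Chem.SanitizeMol(sub)
    mapping = {old: new for new, old in enumerate(sorted(keep))}
    return sub, mapping


def perceive_molecule(
    raw_structure,
    mol_id: str,
    som_labels: Optional[Sequence[int]] = None,
    type_table: Optional[SybylTypeTable] = None,
    on_unknown_type: str = "reject",
) -> MoleculeRecord:
    """Perceive a structure into a typed heavy-atom :class:`MoleculeRecord`.

    Parameters
    ----------
    raw_structure:
        An RDKit ``Mol`` (e.g. one SDF record) or a SMILES string.
    som_labels:
        Optional 0-based heavy-atom indices of annotated sites of metabolism,
        referring to the input heavy-atom order.
    on_unknown_type:
        ``"reject"`` (default) raises on elements outside the type table;
        ``"any"`` maps them to the catch-all ``Any`` type.

    Raises
    ------
    PerceptionError
        On parse/sanitization/valence failure, unknown elements under the
        reject policy, or label indices outside the heavy-atom range.
    """
    table = type_table or SybylTypeTable.default()

    if isinstance(raw_structure, str):
        mol = Chem.MolFromSmiles(raw_structure)
        if mol is None:
            raise PerceptionError(f"molecule {mol_id}: unparsable SMILES {raw_structure!r}")
    elif isinstance(raw_structure, Chem.Mol):
        mol = Chem.Mol(raw_structure)
        try:
            Chem.SanitizeMol(mol)
        except Exception as exc:  # rdkit raises several exception types
            raise PerceptionError(f"molecule {mol_id}: sanitization failed: {exc}") from exc
        mol = Chem.RemoveHs(mol)
    else:
        raise PerceptionError(f"molecule {mol_id}: unsupported input {type(raw_structure)!r}")

    if mol.GetNumAtoms() == 0:
        raise PerceptionError(f"molecule {mol_id}: no heavy atoms")

    mol, index_map = _largest_fragment(mol, mol_id)

    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)

    atoms = [
        AtomRecord(
            element=a.GetSymbol(),
            implicit_h_count=a.GetTotalNumHs(),
            formal_charge=a.GetFormalCharge(),
            aromatic=a.GetIsAromatic(),
            hybridization=_hybridization_of(a),
        )
        for a in mol.GetAtoms()
    ]
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        order = int(round(kek.GetBondBetweenAtoms(i, j).GetBondTypeAsDouble()))
        bonds.append(BondRecord(min(i, j), max(i, j), order, b.GetIsAromatic()))

    labels: Optional[frozenset[int]] = None
    if som_labels is not None:
        mapped = set()
        for idx in som_labels:
            if idx < 0 or (idx not in index_map and idx >= max(index_map) + 1):
                raise PerceptionError(
                    f"molecule {mol_id}: SOM label index {idx} outside heavy-atom range"
                )
            if idx not in index_map:
                log.warning(
                    "molecule %s: SOM label %d was on a removed fragment, dropped",
                    mol_id, idx,
                )
                continue
            mapped.add(index_map[idx])
        labels = frozenset(mapped)

    record = MoleculeRecord(mol_id=mol_id, atoms=atoms, bonds=bonds,
                            som_labels=labels, rdmol=mol)
    for i, atom in enumerate(record.atoms):
        atom.sybyl_type = assign_sybyl_type(record, i, table, on_unknown=on_unknown_type)
    return record


def _is_amide_nitrogen(mol: MoleculeRecord, i: int) -> bool:
    for j, order, _ in mol.neighbors(i):
        if mol.atoms[j].element != "C" or order != 1:
            continue
        for k, o2, _ in mol.neighbors(j):
            if k != i and o2 == 2 and mol.atoms[k].element in ("O", "S"):
                return True
    return False


def _is_carboxylate_oxygen(mol: MoleculeRecord, i: int) -> bool:
    """O belonging to a -C(=O)O(-) / -P(=O)O(-) group with a negative oxygen."""
    if len(mol.neighbors(i)) != 1:
        return False
    (c, _, _), = mol.neighbors(i)
    if mol.atoms[c].element not in ("C", "P"):
        return False
    terminal_os = [
        k for k, _, _ in mol.neighbors(c)
        if mol.atoms[k].element == "O" and len(mol.neighbors(k)) == 1
    ]
    if len(terminal_os) < 2:
        return False
    return any(mol.atoms[k].formal_charge < 0 for k in terminal_os)


def assign_sybyl_type(
    mol: MoleculeRecord,
    atom_index: int,
    type_table: Optional[SybylTypeTable] = None,
    on_unknown: str = "reject",
) -> SybylType:
    """Deterministic (element, hybridization, aromaticity, context) -> type.

    The mapping depends only on the rooted graph, so it is invariant to
    input atom renumbering.
    """
    table = type_table or SybylTypeTable.default()
    a = mol.atoms[atom_index]
    el = a.element
    nbrs = mol.neighbors(atom_index)
    code: Optional[str] = None

    if el == "C":
        if a.aromatic:
            code = "C.ar"
        elif (
            a.formal_charge == 1
            and len(nbrs) == 3
            and all(mol.atoms[j].element == "N" for j, _, _ in nbrs)
        ):
            code = "C.cat"  # guanidinium-type carbocation
        elif a.hybridization == Hybridization.SP:
            code = "C.1"
        elif a.hybridization == Hybridization.SP2:
            code = "C.2"
        else:
            code = "C.3"
    elif el == "N":
        if a.aromatic:
            code = "N.ar"
        elif _is_amide_nitrogen(mol, atom_index):
            code = "N.am"
        elif a.hybridization == Hybridization.SP:
            code = "N.1"
        elif len(nbrs) + a.implicit_h_count == 4 or a.formal_charge == 1:
            code = "N.4"
        elif a.hybridization == Hybridization.SP2:
            code = "N.2"
        elif any(mol.atoms[j].aromatic for j, _, _ in nbrs):
            code = "N.pl3"  # aniline-type: planar by conjugation
        else:
            code = "N.3"
    elif el == "O":
        if _is_carboxylate_oxygen(mol, atom_index):
            code = "O.co2"
        elif any(order == 2 for _, order, _ in nbrs) or a.aromatic:
            code = "O.2"
        else:
            code = "O.3"
    elif el == "S":
        dbl_o = sum(
            1 for j, order, _ in nbrs
            if order == 2 and mol.atoms[j].element == "O"
        )
        if dbl_o >= 2:
            code = "S.O2"
        elif dbl_o == 1:
            code = "S.O"
        elif any(order == 2 for _, order, _ in nbrs) or a.aromatic:
            code = "S.2"
        else:
            code = "S.3"
    elif el == "P":
        code = "P.3"
    elif el in ("F", "Cl", "Br", "I"):
        code = el
    elif el == "Si":
        code = "Si.3"

    if code is None or code not in table:
        if on_unknown == "any" and "Any" in table:
            log.warning(
                "molecule %s atom %d (%s): no specific SYBYL type, using Any",
                mol.mol_id, atom_index, el,
            )
            return table.get("Any")
        raise PerceptionError(
            f"molecule {mol.mol_id}: atom {atom_index} ({el}) has no SYBYL type in table"
        )
    return table.get(code)


def topological_distances(mol: MoleculeRecord) -> np.ndarray:
    """All-pairs shortest bond-path lengths on the heavy-atom graph.

    Breadth-first search from each atom; entries for atom pairs in different
    fragments carry the :data:`UNREACHABLE` sentinel.
    """
    n = mol.n_atoms
    dist = np.full((n, n), UNREACHABLE, dtype=np.int64)
    adj = [[j for j, _, _ in mol.neighbors(i)] for i in range(n)]
    for src in range(n):
        dist[src, src] = 0
        frontier = [src]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if dist[src, v] == UNREACHABLE:
                        dist[src, v] = d
                        nxt.append(v)
            frontier = nxt
    return dist
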