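"""Synthetic SOM-labeled molecules for training, evaluation, and testing.

Real SOM annotations come from curated metabolic-reaction databases that
cannot be redistributed.  This generator emulates their shape: drug-like
small organics (5-25 heavy atoms, built from a weighted fragment grammar
of alkyl chains, ethers, amines, aromatics, and halides) with per-atom
labels produced by a deterministic structure -> label rule, so the label
signal is detectable from the rooted fingerprint by construction.

Default label rules, applied in order:

1. alpha-carbon rule: a non-aromatic carbon bonded to an ether oxygen
   (O with two heavy neighbors, single bonds) or to an aliphatic amine
   nitrogen is a SOM;
2. ortho-hydrogen rule: an aromatic carbon with at least one implicit
   hydrogen whose aromatic neighbor carries a non-ring heavy substituent
   is a SOM.

Labels can then be flipped i.i.d. with probability ``label_noise`` to
emulate annotation error.  Everything is deterministic under
``(spec, seed)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from rdkit import Chem

from .chem_core import MoleculeRecord, PerceptionError, SomkitError, perceive_molecule

log = logging.getLogger(__name__)

MAX_BUILD_RETRIES = 25


class FixtureError(SomkitError):
    pass


def rule_alpha_to_heteroatom(mol: MoleculeRecord, atom: int) -> bool:
    """Non-aromatic carbon alpha to an ether oxygen or aliphatic amine nitrogen."""
    a = mol.atoms[atom]
    if a.element != "C" or a.aromatic:
        return False
    for j, order, _ in mol.neighbors(atom):
        nb = mol.atoms[j]
        if nb.aromatic or order != 1:
            continue
        if nb.element == "O" and len(mol.neighbors(j)) == 2:
            return True
        if nb.element == "N" and nb.sybyl_type is not None and \
                nb.sybyl_type.code in ("N.3", "N.pl3"):
            return True
    return False


def rule_ortho_to_substituent(mol: MoleculeRecord, atom: int) -> bool:
    """Aromatic C-H ortho to a ring atom bearing a non-ring substituent."""
    a = mol.atoms[atom]
    if a.element != "C" or not a.aromatic or a.implicit_h_count < 1:
        return False
    for j, _, _ in mol.neighbors(atom):
        if not mol.atoms[j].aromatic:
            continue
        for k, _, _ in mol.neighbors(j):
            if k != atom and not mol.atoms[k].aromatic:
                return True
    return False


DEFAULT_LABEL_RULES: tuple[Callable[[MoleculeRecord, int], bool], ...] = (
    rule_alpha_to_heteroatom,
    rule_ortho_to_substituent,
)


@dataclass(frozen=True)
class FixtureSpec:
    n_molecules: int = 400
    seed: int = 0
    label_rules: tuple[Callable[[MoleculeRecord, int], bool], ...] = DEFAULT_LABEL_RULES
    label_noise: float = 0.0
    #: weights for (aromatic scaffold, plain chain) molecules
    p_aromatic: float = 0.55
    #: per-position heteroatom substitution probability inside chains
    p_heteroatom: float = 0.25
    #: probability that a chain terminus becomes a halide
    p_halide: float = 0.15

    def __post_init__(self):
        if not 0.0 <= self.label_noise < 0.5:
            raise FixtureError("label_noise must be in [0, 0.5)")
        if self.n_molecules < 1:
            raise FixtureError("n_molecules must be >= 1")


def _random_chain(rng: np.random.Generator, length: int, spec: FixtureSpec) -> list[str]:
    """A path of element symbols; no adjacent heteroatoms; optional halide cap."""
    symbols = ["C"]
    for _ in range(length - 1):
        if symbols[-1] == "C" and rng.random() < spec.p_heteroatom:
            symbols.append("O" if rng.random() < 0.5 else "N")
        else:
            symbols.append("C")
    if symbols[-1] == "C" and length > 1 and rng.random() < spec.p_halide:
        symbols[-1] = str(rng.choice(["F", "Cl", "Br"]))
    return symbols


_ATOMIC_NUM = {"C": 6, "N": 7, "O": 8, "F": 9, "Cl": 17, "Br": 35}


def _append_chain(rw: Chem.RWMol, anchor: int, symbols: Sequence[str]) -> None:
    prev = anchor
    for sym in symbols:
        idx = rw.AddAtom(Chem.Atom(_ATOMIC_NUM[sym]))
        rw.AddBond(prev, idx, Chem.BondType.SINGLE)
        prev = idx


def _build_random_rdmol(rng: np.random.Generator, spec: FixtureSpec) -> Chem.Mol:
    rw = Chem.RWMol()
    if rng.random() < spec.p_aromatic:
        ring = [rw.AddAtom(Chem.Atom(6)) for _ in range(6)]
        orders = [Chem.BondType.DOUBLE, Chem.BondType.SINGLE] * 3
        for i in range(6):
            rw.AddBond(ring[i], ring[(i + 1) % 6], orders[i])
        n_sub = int(rng.integers(1, 4))
        positions = rng.choice(6, size=n_sub, replace=False)
        for pos in sorted(int(p) for p in positions):
            chain = _random_chain(rng, int(rng.integers(1, 5)), spec)
            _append_chain(rw, ring[pos], chain)
    else:
        length = int(rng.integers(5, 10))
        symbols = _random_chain(rng, length, spec)
        first = rw.AddAtom(Chem.Atom(_ATOMIC_NUM[symbols[0]]))
        _append_chain(rw, first, symbols[1:])
        if rng.random() < 0.5:
            # one branch at a random carbon with spare valence
            carbons = [
                a.GetIdx() for a in rw.GetAtoms()
                if a.GetSymbol() == "C" and a.GetDegree() <= 2
            ]
            if carbons:
                anchor = int(rng.choice(carbons))
                _append_chain(rw, anchor, _random_chain(rng, int(rng.integers(1, 4)), spec))
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def apply_label_rules(
    mol: MoleculeRecord,
    rules: Sequence[Callable[[MoleculeRecord, int], bool]] = DEFAULT_LABEL_RULES,
) -> frozenset[int]:
    return frozenset(
        i for i in range(mol.n_atoms) if any(rule(mol, i) for rule in rules)
    )


def generate(spec: FixtureSpec) -> list[MoleculeRecord]:
    """Generate ``spec.n_molecules`` labeled molecules, deterministically."""
    rng = np.random.default_rng(spec.seed)
    mols: list[MoleculeRecord] = []
    any_rule_fired = False
    for n in range(spec.n_molecules):
        record = None
        for _ in range(MAX_BUILD_RETRIES):
            try:
                rdmol = _build_random_rdmol(rng, spec)
                record = perceive_molecule(rdmol, f"FIX{n:05d}")
                break
            except (PerceptionError, Chem.rdchem.MolSanitizeException,
                    ValueError) as exc:
                log.debug("fixture resample after invalid structure: %s", exc)
        if record is None:
            raise FixtureError(f"could not build a valid molecule for index {n}")
        labels = set(apply_label_rules(record, spec.label_rules))
        if labels:
            any_rule_fired = True
        if spec.label_noise > 0:
            flips = rng.random(record.n_atoms) < spec.label_noise
            for i in np.nonzero(flips)[0]:
                i = int(i)
                labels.symmetric_difference_update({i})
        record.som_labels = frozenset(labels)
        mols.append(record)
    if not any_rule_fired:
        raise FixtureError("no label rule fired on any generated molecule")
    return mols


def skeleton_key(mol: MoleculeRecord) -> str:
    """Stereo-agnostic canonical identifier used for duplicate grouping."""
    if mol.rdmol is None:
        raise FixtureError(f"molecule {mol.mol_id} carries no structure object")
    return Chem.MolToSmiles(Chem.Mol(mol.rdmol), isomericSmiles=False)


def split(
    mols: Sequence[MoleculeRecord],
    fractions: tuple[float, float],
    seed: int,
) -> tuple[list[MoleculeRecord], list[MoleculeRecord]]:
    """Molecule-level train/test split with duplicate co-partitioning.

    Records sharing a stereo-agnostic canonical identifier always land in
    the same partition, so near-duplicates can never straddle the split.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise FixtureError("fractions must sum to 1")
    groups: dict[str, list[MoleculeRecord]] = {}
    for m in mols:
        groups.setdefault(skeleton_key(m), []).append(m)
    keys = sorted(groups)
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    n_train_target = fractions[0] * len(keys)
    train: list[MoleculeRecord] = []
    test: list[MoleculeRecord] = []
    taken = 0
    for key in keys:
        if taken < round(n_train_target):
            train.extend(groups[key])
            taken += 1
        else:
            test.extend(groups[key])
    if not train or not test:
        raise FixtureError("split produced an empty partition")
    return train, test
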