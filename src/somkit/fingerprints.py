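"""Rooted circular atom fingerprints.

Two equivalent encodings of the same rooted environment:

* the binary block encoding: every (bond distance, atom type) combination
  owns a 32-bit block, and the first ``n`` bits of block ``(d, t)`` are set
  when the root has ``n`` neighbors of type ``t`` at distance ``d``
  (saturating at 32);
* the count encoding: the exact neighbor count per (distance, type) pair,
  with no clamping.

The block layout is distance-major, type-ordinal-minor:
``block_index = d * T + t`` for a type table of size ``T``.  The layout is
part of the feature schema serialized with trained models, so training and
prediction can never drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_core import MoleculeRecord, SomkitError

BITS_PER_BLOCK = 32


class FingerprintError(SomkitError):
    pass


@dataclass(frozen=True)
class CountFingerprint:
    """Exact (distance, type) neighbor counts, length T * (radius + 1)."""

    counts: np.ndarray
    n_types: int
    radius: int

    def count(self, distance: int, type_ordinal: int) -> int:
        return int(self.counts[distance * self.n_types + type_ordinal])


@dataclass(frozen=True)
class FameBinaryFingerprint:
    """32-bit-block binary encoding, length T * (radius + 1) * 32."""

    bits: np.ndarray  # uint8 vector of 0/1
    n_types: int
    radius: int

    def block(self, distance: int, type_ordinal: int) -> np.ndarray:
        start = (distance * self.n_types + type_ordinal) * BITS_PER_BLOCK
        return self.bits[start:start + BITS_PER_BLOCK]


def _type_counts_by_distance(mol: MoleculeRecord, root: int, radius: int) -> np.ndarray:
    if not 0 <= root < mol.n_atoms:
        raise FingerprintError(f"root atom {root} out of range for {mol.mol_id}")
    if radius < 0:
        raise FingerprintError("radius must be >= 0")
    n_types = _table_size(mol)
    counts = np.zeros((radius + 1) * n_types, dtype=np.int64)
    dist_row = mol.distances()[root]
    for j, atom in enumerate(mol.atoms):
        d = dist_row[j]
        if d <= radius:
            counts[int(d) * n_types + atom.sybyl_type.ordinal] += 1
    return counts


def _table_size(mol: MoleculeRecord) -> int:
    ordinals = []
    for atom in mol.atoms:
        if atom.sybyl_type is None:
            raise FingerprintError(f"molecule {mol.mol_id} has untyped atoms")
        ordinals.append(atom.sybyl_type.ordinal)
    # The table size is carried by the caller in practice; infer a safe
    # minimum here only when the molecule is used standalone.
    return max(ordinals) + 1


def count_fingerprint(
    mol: MoleculeRecord, root: int, radius: int, n_types: int | None = None
) -> CountFingerprint:
    """Exact rooted circular count fingerprint (root included at distance 0)."""
    counts = _type_counts_by_distance(mol, root, radius)
    inferred = counts.size // (radius + 1)
    if n_types is not None:
        if n_types < inferred:
            raise FingerprintError(
                f"type table of size {n_types} too small for molecule {mol.mol_id}"
            )
        padded = np.zeros((radius + 1) * n_types, dtype=np.int64)
        for d in range(radius + 1):
            padded[d * n_types: d * n_types + inferred] = \
                counts[d * inferred: (d + 1) * inferred]
        counts = padded
    else:
        n_types = inferred
    return CountFingerprint(counts=counts, n_types=n_types, radius=radius)


def fame_binary_fingerprint(
    mol: MoleculeRecord, root: int, radius: int, n_types: int | None = None
) -> FameBinaryFingerprint:
    """Binary block fingerprint: prefix bits set per (distance, type) count."""
    cfp = count_fingerprint(mol, root, radius, n_types=n_types)
    bits = np.zeros(cfp.counts.size * BITS_PER_BLOCK, dtype=np.uint8)
    nonzero = np.nonzero(cfp.counts)[0]
    for blk in nonzero:
        n = min(BITS_PER_BLOCK, int(cfp.counts[blk]))
        bits[blk * BITS_PER_BLOCK: blk * BITS_PER_BLOCK + n] = 1
    return FameBinaryFingerprint(bits=bits, n_types=cfp.n_types, radius=radius)


def binary_feature_names(type_codes: tuple[str, ...], radius: int) -> list[str]:
    return [
        f"fp_d{d}_{code}_b{b}"
        for d in range(radius + 1)
        for code in type_codes
        for b in range(BITS_PER_BLOCK)
    ]


def count_feature_names(type_codes: tuple[str, ...], radius: int) -> list[str]:
    return [f"cnt_d{d}_{code}" for d in range(radius + 1) for code in type_codes]
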