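"""Assembly of per-atom feature tables (fingerprint + descriptors).

The feature schema — the exact ordered list of named columns — is built
here and serialized with every trained model; training and prediction
refuse to proceed if their schemas differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import descriptors as desc
from .chem_core import MoleculeRecord, SomkitError, SybylTypeTable
from .fingerprints import (
    binary_feature_names,
    count_feature_names,
    count_fingerprint,
    fame_binary_fingerprint,
)

META_COLUMNS = ("mol_id", "atom_idx", "element", "sybyl_type")
LABEL_COLUMN = "som_label"

FINGERPRINT_KINDS = ("fame_binary", "count")


class FeaturizationError(SomkitError):
    pass


@dataclass(frozen=True)
class FeaturizationConfig:
    """What goes into the per-atom feature vector."""

    radius: int = 5
    fingerprint_kind: str = "fame_binary"
    descriptor_slots: tuple[str, ...] = desc.PHYSCHEM_SLOTS
    type_codes: tuple[str, ...] = field(
        default_factory=lambda: SybylTypeTable.default().codes
    )

    def __post_init__(self):
        if self.fingerprint_kind not in FINGERPRINT_KINDS:
            raise FeaturizationError(
                f"unknown fingerprint kind {self.fingerprint_kind!r}"
            )
        if self.radius < 0:
            raise FeaturizationError("radius must be >= 0")
        # configuration-time provider check (fails at startup, not at compute)
        desc.resolve_providers(self.descriptor_slots)

    @property
    def type_table(self) -> SybylTypeTable:
        return SybylTypeTable(self.type_codes)

    def feature_names(self) -> list[str]:
        if self.fingerprint_kind == "fame_binary":
            fp = binary_feature_names(self.type_codes, self.radius)
        else:
            fp = count_feature_names(self.type_codes, self.radius)
        physchem = [s for s in desc.PHYSCHEM_SLOTS if s in self.descriptor_slots]
        return fp + physchem + list(desc.TOPO_SLOTS)


def featurize_molecule(mol: MoleculeRecord, cfg: FeaturizationConfig) -> np.ndarray:
    """(n_atoms, n_features) float32 matrix in schema order."""
    n_types = len(cfg.type_codes)
    rows = []
    for i in range(mol.n_atoms):
        if cfg.fingerprint_kind == "fame_binary":
            fp = fame_binary_fingerprint(mol, i, cfg.radius, n_types=n_types).bits
        else:
            fp = count_fingerprint(mol, i, cfg.radius, n_types=n_types).counts
        rows.append(fp.astype(np.float32))
    fp_mat = np.vstack(rows)
    pc_mat = desc.physchem_matrix(mol, cfg.descriptor_slots).astype(np.float32)
    topo_mat = desc.topo_matrix(mol).astype(np.float32)
    return np.hstack([fp_mat, pc_mat, topo_mat])


def binary_fingerprint_matrix(mol: MoleculeRecord, radius: int, n_types: int) -> np.ndarray:
    """Per-atom binary fingerprints as a uint8 matrix (for reliability)."""
    return np.vstack([
        fame_binary_fingerprint(mol, i, radius, n_types=n_types).bits
        for i in range(mol.n_atoms)
    ])


def build_feature_table(
    mols: Sequence[MoleculeRecord],
    cfg: FeaturizationConfig,
    with_labels: bool = True,
) -> pd.DataFrame:
    """One row per heavy atom: metadata, named features, optional labels.

    ``atom_idx`` is 0-based here (internal convention); writers convert to
    1-based for user-facing files.
    """
    names = cfg.feature_names()
    frames = []
    for mol in mols:
        feats = featurize_molecule(mol, cfg)
        df = pd.DataFrame(feats, columns=names)
        df.insert(0, "mol_id", mol.mol_id)
        df.insert(1, "atom_idx", np.arange(mol.n_atoms))
        df.insert(2, "element", [a.element for a in mol.atoms])
        df.insert(3, "sybyl_type", [a.sybyl_type.code for a in mol.atoms])
        if with_labels:
            labels = mol.som_labels if mol.som_labels is not None else frozenset()
            df[LABEL_COLUMN] = [int(i in labels) for i in range(mol.n_atoms)]
        frames.append(df)
    if not frames:
        raise FeaturizationError("no molecules to featurize")
    return pd.concat(frames, ignore_index=True)


def check_schema(expected: Sequence[str], actual: Sequence[str]) -> None:
    if list(expected) != list(actual):
        raise FeaturizationError(
            "feature schema mismatch:\n"
            f"  model schema ({len(expected)} cols): {_preview(expected)}\n"
            f"  requested schema ({len(actual)} cols): {_preview(actual)}"
        )


def _preview(cols: Sequence[str], limit: int = 6) -> str:
    cols = list(cols)
    if len(cols) <= limit:
        return ", ".join(cols)
    return ", ".join(cols[:limit]) + f", ... ({len(cols) - limit} more)"
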