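"""Readers and writers: SDF V2000 with per-atom SOM labels, SMILES lists,
prediction CSV, and JSON metric reports.

Conventions
-----------
* SOM annotations travel as the SD property ``<SOM_LABELS>``: comma-
  separated 1-based heavy-atom indices (SDF atom blocks are 1-based);
  an absent property means an unlabeled molecule.
* Internally all indices are 0-based; writers convert back.
* CSV output is comma-separated UTF-8 with a header row, LF line endings,
  and probabilities printed with 6 decimals, so identical runs produce
  byte-identical files.
* Every artifact written by the CLI embeds the resolved configuration
  (provenance): a ``# somkit ...`` comment line in CSV, a ``config`` key
  in JSON, a ``<SOMKIT_PROVENANCE>`` property in SDF.
"""

from __future__ import annotations

import json
import logging
from typing import Optional, Sequence

from rdkit import Chem

from .chem_core import (
    MoleculeRecord,
    PerceptionError,
    SomkitError,
    SybylTypeTable,
    perceive_molecule,
)
from .som_model import SomPrediction

log = logging.getLogger(__name__)

SOM_PROPERTY = "SOM_LABELS"
PROVENANCE_PROPERTY = "SOMKIT_PROVENANCE"

PREDICTION_COLUMNS = ("mol_id", "atom_idx", "element", "probability", "call", "rank")
RELIABILITY_COLUMNS = ("fame_score", "shannon_entropy")


class FormatError(SomkitError):
    pass


def _parse_som_property(raw: str, n_atoms: int, mol_id: str) -> list[int]:
    indices = []
    for token in raw.replace(";", ",").split(","):
        token = token.strip()
        if not token:
            continue
        try:
            one_based = int(token)
        except ValueError:
            raise PerceptionError(f"molecule {mol_id}: bad SOM label token {token!r}")
        if not 1 <= one_based <= n_atoms:
            raise PerceptionError(
                f"molecule {mol_id}: SOM label {one_based} exceeds heavy-atom count {n_atoms}"
            )
        indices.append(one_based - 1)
    return indices


def read_labeled_sdf(
    path: str,
    type_table: Optional[SybylTypeTable] = None,
) -> list[MoleculeRecord]:
    """Read a multi-record V2000 SDF; malformed records are skipped and counted."""
    supplier = Chem.SDMolSupplier(path, removeHs=True, sanitize=False)
    records: list[MoleculeRecord] = []
    n_read = n_skipped = 0
    for i, raw in enumerate(supplier):
        n_read += 1
        if raw is None:
            n_skipped += 1
            log.warning("%s: record %d unparsable, skipped", path, i + 1)
            continue
        mol_id = raw.GetProp("_Name") if raw.HasProp("_Name") and raw.GetProp("_Name") \
            else f"MOL{i + 1:05d}"
        labels: Optional[list[int]] = None
        try:
            heavy = sum(1 for a in raw.GetAtoms() if a.GetAtomicNum() > 1)
            if raw.HasProp(SOM_PROPERTY):
                labels = _parse_som_property(raw.GetProp(SOM_PROPERTY), heavy, mol_id)
            records.append(
                perceive_molecule(raw, mol_id, som_labels=labels, type_table=type_table)
            )
        except PerceptionError as exc:
            n_skipped += 1
            log.warning("%s: record %d (%s) rejected: %s", path, i + 1, mol_id, exc)
    log.info("%s: read %d records, kept %d, skipped %d",
             path, n_read, len(records), n_skipped)
    if not records:
        raise FormatError(f"{path}: no valid records")
    return records


def read_smiles_file(
    path: str,
    type_table: Optional[SybylTypeTable] = None,
) -> list[MoleculeRecord]:
    """One SMILES per line, optional tab-separated molecule identifier."""
    records = []
    n_read = n_skipped = 0
    with open(path, "r", encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            n_read += 1
            parts = line.split("\t")
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 and parts[1] else f"MOL{i + 1:05d}"
            try:
                records.append(perceive_molecule(smiles, mol_id, type_table=type_table))
            except PerceptionError as exc:
                n_skipped += 1
                log.warning("%s: line %d rejected: %s", path, i + 1, exc)
    log.info("%s: read %d records, kept %d, skipped %d",
             path, n_read, len(records), n_skipped)
    if not records:
        raise FormatError(f"{path}: no valid records")
    return records


def write_labeled_sdf(
    mols: Sequence[MoleculeRecord],
    path: str,
    provenance: Optional[dict] = None,
) -> None:
    """Write records as V2000 SDF with 1-based ``<SOM_LABELS>`` properties."""
    writer = Chem.SDWriter(path)
    writer.SetForceV3000(False)
    try:
        for mol in mols:
            if mol.rdmol is None:
                raise FormatError(
                    f"molecule {mol.mol_id} carries no structure object to write"
                )
            out = Chem.Mol(mol.rdmol)
            out.SetProp("_Name", mol.mol_id)
            if mol.som_labels is not None:
                out.SetProp(
                    SOM_PROPERTY,
                    ",".join(str(i + 1) for i in sorted(mol.som_labels)),
                )
            if provenance is not None:
                out.SetProp(PROVENANCE_PROPERTY, json.dumps(provenance, sort_keys=True))
            writer.write(out)
    finally:
        writer.close()


def write_predictions(
    predictions: Sequence[SomPrediction],
    path: str,
    provenance: Optional[dict] = None,
) -> None:
    """Fixed-order prediction CSV; reliability columns only when scored.

    ``atom_idx`` is written 1-based.  Mixing scored and unscored
    predictions in one file is an error: the schema is all-or-nothing.
    """
    with_rel = [p.reliability is not None for p in predictions]
    if any(with_rel) and not all(with_rel):
        raise FormatError("mixed reliability availability across predictions")
    reliability = bool(predictions) and all(with_rel)
    columns = PREDICTION_COLUMNS + (RELIABILITY_COLUMNS if reliability else ())
    lines = []
    if provenance is not None:
        lines.append("# somkit " + json.dumps(provenance, sort_keys=True))
    lines.append(",".join(columns))
    for p in predictions:
        row = [
            p.mol_id,
            str(p.atom_idx + 1),
            p.element,
            f"{p.probability:.6f}",
            str(int(p.call)),
            str(p.rank),
        ]
        if reliability:
            row += [
                f"{p.reliability.fame_score:.6f}",
                f"{p.reliability.shannon_entropy:.6f}",
            ]
        lines.append(",".join(row))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_predictions(path: str) -> list[SomPrediction]:
    """Read a prediction CSV back into :class:`SomPrediction` objects."""
    import pandas as pd

    from .reliability import ReliabilityScores

    df = pd.read_csv(path, comment="#")
    missing = [c for c in PREDICTION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing prediction columns {missing}")
    reliability = all(c in df.columns for c in RELIABILITY_COLUMNS)
    out = []
    for row in df.itertuples(index=False):
        rel = None
        if reliability:
            rel = ReliabilityScores(
                fame_score=float(row.fame_score),
                shannon_entropy=float(row.shannon_entropy),
            )
        out.append(SomPrediction(
            mol_id=str(row.mol_id),
            atom_idx=int(row.atom_idx) - 1,
            element=str(row.element),
            probability=float(row.probability),
            call=bool(row.call),
            rank=int(row.rank),
            reliability=rel,
        ))
    return out


def write_json_report(payload: dict, path: str, provenance: Optional[dict] = None) -> None:
    """JSON report; NaN (undefined metric) values become nulls."""
    doc = dict(payload)
    if provenance is not None:
        doc = {"config": provenance, **doc}
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(_sanitize(doc), fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")


def _sanitize(obj):
    import math

    import numpy as np

    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        obj = float(obj)
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
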