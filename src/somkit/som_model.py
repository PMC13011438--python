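"""Trainable random-forest site-of-metabolism classifier.

Every heavy atom of a labeled molecule is a training instance: annotated
atoms are positives, all remaining atoms of the same molecule negatives.
Molecules without any annotation are excluded from training.  Predictions
are fully deterministic: a fixed seed reproduces bit-identical outputs.

A trained model is a self-contained bundle — forest state, the ordered
feature schema, the training configuration, and the binary fingerprints of
all training atoms (so applicability-domain scoring never needs the raw
training structures).
"""

from __future__ import annotations

import hashlib
import logging
import pickle
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import descriptors as desc
from .chem_core import MoleculeRecord, SomkitError
from .features import (
    FeaturizationConfig,
    LABEL_COLUMN,
    binary_fingerprint_matrix,
    build_feature_table,
    check_schema,
    featurize_molecule,
)
from .reliability import (
    ReliabilityConfig,
    ReliabilityScores,
    fame_scores_matrix,
    shannon_entropy,
)

log = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = "somkit-model-1"


class ModelError(SomkitError):
    pass


@dataclass(frozen=True)
class TrainingConfig:
    radius: int = 5
    fingerprint_kind: str = "fame_binary"
    n_trees: int = 250
    max_features: str = "sqrt"
    class_weight: str = "balanced"
    threshold: float = 0.3
    seed: int = 0
    descriptor_slots: tuple[str, ...] = desc.PHYSCHEM_SLOTS

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ModelError("threshold must be in (0, 1)")
        if self.n_trees < 1:
            raise ModelError("n_trees must be >= 1")

    def featurization(self) -> FeaturizationConfig:
        return FeaturizationConfig(
            radius=self.radius,
            fingerprint_kind=self.fingerprint_kind,
            descriptor_slots=tuple(self.descriptor_slots),
        )


@dataclass
class SomPrediction:
    mol_id: str
    atom_idx: int  # 0-based internal index
    element: str
    probability: float
    call: bool
    rank: int
    reliability: Optional[ReliabilityScores] = None


@dataclass
class TrainedModel:
    forest: RandomForestClassifier
    feature_schema: list[str]
    config: TrainingConfig
    reference_fingerprints: Optional[np.ndarray]  # packed bits, uint8
    reference_n_bits: int
    version: str = MODEL_FORMAT_VERSION

    def reference_matrix(self) -> np.ndarray:
        if self.reference_fingerprints is None:
            raise ModelError(
                "model bundle carries no reference fingerprints; "
                "reliability scoring is unavailable"
            )
        unpacked = np.unpackbits(self.reference_fingerprints, axis=1)
        return unpacked[:, : self.reference_n_bits]


def train(
    dataset,
    cfg: TrainingConfig = TrainingConfig(),
) -> TrainedModel:
    """Fit the forest on labeled molecules (or a prebuilt feature table).

    ``dataset`` is either a sequence of labeled :class:`MoleculeRecord`
    (the usual path: featurization and reference-fingerprint extraction
    happen here) or a feature ``DataFrame`` from
    :func:`somkit.features.build_feature_table` (no reference fingerprints
    are then available for reliability scoring).
    """
    fz = cfg.featurization()
    if isinstance(dataset, pd.DataFrame):
        table = dataset
        ref_packed, n_bits = None, 0
    else:
        mols = [m for m in dataset if m.som_labels]
        dropped = len(list(dataset)) - len(mols)
        if dropped:
            log.info("excluded %d molecules without SOM annotations from training", dropped)
        if not mols:
            raise ModelError("no labeled molecules to train on")
        table = build_feature_table(mols, fz, with_labels=True)
        ref = np.vstack([
            binary_fingerprint_matrix(m, cfg.radius, len(fz.type_codes)) for m in mols
        ])
        n_bits = ref.shape[1]
        ref_packed = np.packbits(ref, axis=1)

    schema = fz.feature_names()
    missing = [c for c in schema + [LABEL_COLUMN] if c not in table.columns]
    if missing:
        raise ModelError(f"training table lacks required columns: {missing[:5]}")
    y = table[LABEL_COLUMN].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ModelError("training data contains a single class")
    X = table[schema].to_numpy(dtype=np.float32)

    forest = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=cfg.max_features,
        class_weight=cfg.class_weight,
        random_state=cfg.seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return TrainedModel(
        forest=forest,
        feature_schema=schema,
        config=cfg,
        reference_fingerprints=ref_packed,
        reference_n_bits=n_bits,
    )


def rank_probabilities(probs: Sequence[float]) -> list[int]:
    """Within-molecule ranks: descending probability, ties by atom index.

    Ranks are a permutation of 1..n_atoms.
    """
    order = np.lexsort((np.arange(len(probs)), -np.asarray(probs)))
    ranks = np.empty(len(probs), dtype=int)
    ranks[order] = np.arange(1, len(probs) + 1)
    return ranks.tolist()


def predict(
    model: TrainedModel,
    mols: Sequence[MoleculeRecord],
    with_reliability: bool = False,
    reliability_cfg: ReliabilityConfig = ReliabilityConfig(),
) -> list[SomPrediction]:
    """Per-atom probabilities, thresholded calls (p >= threshold), ranks.

    Unfeaturizable molecules are skipped with a logged reason; the run
    continues.  Outputs are independent of molecule order.
    """
    fz = model.config.featurization()
    check_schema(model.feature_schema, fz.feature_names())
    if with_reliability:
        reference = model.reference_matrix()
    positive_col = _positive_column(model.forest)

    out: list[SomPrediction] = []
    for mol in mols:
        try:
            X = featurize_molecule(mol, fz)
        except SomkitError as exc:
            log.warning("skipping molecule %s: %s", mol.mol_id, exc)
            continue
        probs = model.forest.predict_proba(X)[:, positive_col]
        ranks = rank_probabilities(probs)
        rel: list[Optional[ReliabilityScores]] = [None] * mol.n_atoms
        if with_reliability:
            fps = binary_fingerprint_matrix(mol, model.config.radius,
                                            len(fz.type_codes))
            scores = fame_scores_matrix(fps, reference, reliability_cfg)
            rel = [
                ReliabilityScores(
                    fame_score=float(scores[i]),
                    shannon_entropy=shannon_entropy(float(probs[i])),
                )
                for i in range(mol.n_atoms)
            ]
        for i in range(mol.n_atoms):
            p = float(probs[i])
            out.append(SomPrediction(
                mol_id=mol.mol_id,
                atom_idx=i,
                element=mol.atoms[i].element,
                probability=p,
                call=p >= model.config.threshold,
                rank=ranks[i],
                reliability=rel[i],
            ))
    return out


def _positive_column(forest: RandomForestClassifier) -> int:
    classes = list(forest.classes_)
    if 1 not in classes:
        raise ModelError("fitted forest has no positive class")
    return classes.index(1)


def save_model(model: TrainedModel, path: str) -> None:
    """Serialize a model bundle; bit-identical for identical training runs."""
    payload = pickle.dumps({
        "forest": model.forest,
        "feature_schema": model.feature_schema,
        "config": model.config,
        "reference_fingerprints": model.reference_fingerprints,
        "reference_n_bits": model.reference_n_bits,
    }, protocol=4)
    bundle = {
        "format_version": model.version,
        "sha256": hashlib.sha256(payload).hexdigest(),
        "payload": payload,
    }
    with open(path, "wb") as fh:
        pickle.dump(bundle, fh, protocol=4)


def load_model(path: str) -> TrainedModel:
    with open(path, "rb") as fh:
        try:
            bundle = pickle.load(fh)
        except Exception as exc:
            raise ModelError(f"unreadable model bundle {path}: {exc}") from exc
    if not isinstance(bundle, dict) or "format_version" not in bundle:
        raise ModelError(f"{path} is not a somkit model bundle")
    if bundle["format_version"] != MODEL_FORMAT_VERSION:
        raise ModelError(
            f"model format {bundle['format_version']!r} does not match "
            f"supported {MODEL_FORMAT_VERSION!r}"
        )
    payload = bundle["payload"]
    if hashlib.sha256(payload).hexdigest() != bundle["sha256"]:
        raise ModelError(f"model bundle {path} failed its integrity check")
    state = pickle.loads(payload)
    return TrainedModel(
        forest=state["forest"],
        feature_schema=state["feature_schema"],
        config=state["config"],
        reference_fingerprints=state["reference_fingerprints"],
        reference_n_bits=state["reference_n_bits"],
        version=bundle["format_version"],
    )
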