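"""Atom- and molecule-level evaluation of SOM predictions.

Atom level: ROC-AUC (rank formulation with half-credit for ties), PR-AUC
(average precision with step interpolation), F1, Matthews correlation
coefficient, precision and recall at a decision threshold.  Molecule
level: the top-2 correctness rate — the fraction of molecules whose two
highest-ranked atoms contain at least one annotated site of metabolism.

Also provides the reliability comparison report: rank correlation between
the FAME applicability-domain score and the Shannon entropy, and binned
accuracy/MCC against each metric.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    average_precision_score,
    matthews_corrcoef,
    precision_recall_fscore_support,
    roc_auc_score,
)

from .chem_core import SomkitError
from .som_model import SomPrediction

log = logging.getLogger(__name__)


class EvaluationError(SomkitError):
    pass


@dataclass
class MetricsReport:
    roc_auc: float
    pr_auc: float
    f1: float
    mcc: float
    precision: float
    recall: float
    top2: float
    n_atoms: int
    n_molecules: int
    n_positive: int
    threshold: float
    rank_metrics_defined: bool = True
    n_top2_excluded: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def atom_metrics(
    y_true: Sequence[int], y_score: Sequence[float], threshold: float
) -> MetricsReport:
    """Threshold and ranking metrics over a flat per-atom prediction set.

    With single-class labels the ranking metrics (ROC-AUC, PR-AUC) are
    undefined: they are reported as NaN with ``rank_metrics_defined``
    False, while the confusion-matrix metrics are still computed.
    """
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(y_score, dtype=float)
    if y.shape != s.shape:
        raise EvaluationError("labels and scores have different lengths")
    y_pred = (s >= threshold).astype(int)
    precision, recall, f1, _ = precision_recall_fscore_support(
        y, y_pred, average="binary", zero_division=0
    )
    mcc = _safe_mcc(y, y_pred)
    defined = len(np.unique(y)) == 2
    if defined:
        roc = float(roc_auc_score(y, s))
        pr = float(average_precision_score(y, s))
    else:
        log.warning("single-class labels: ranking metrics undefined")
        roc = pr = float("nan")
    return MetricsReport(
        roc_auc=roc,
        pr_auc=pr,
        f1=float(f1),
        mcc=mcc,
        precision=float(precision),
        recall=float(recall),
        top2=float("nan"),
        n_atoms=int(y.size),
        n_molecules=0,
        n_positive=int(y.sum()),
        threshold=threshold,
        rank_metrics_defined=defined,
    )


def _safe_mcc(y: np.ndarray, y_pred: np.ndarray) -> float:
    # sklearn already returns 0 for a zero denominator
    return float(matthews_corrcoef(y, y_pred))


def _group_by_molecule(
    predictions: Sequence[SomPrediction],
) -> dict[str, list[SomPrediction]]:
    groups: dict[str, list[SomPrediction]] = {}
    for p in predictions:
        groups.setdefault(p.mol_id, []).append(p)
    return groups


def top2_correctness(
    predictions: Sequence[SomPrediction],
    labels: dict[str, frozenset[int]],
) -> tuple[float, int, int]:
    """(rate, n_evaluated, n_excluded) over molecules with >= 1 annotated SOM.

    A molecule counts as correct when at least one annotated atom has rank
    1 or 2 (the model's deterministic tie rule already fixed the ranks).
    Molecules with no annotation are excluded; a molecule with fewer than
    two heavy atoms contributes its single top atom.
    """
    groups = _group_by_molecule(predictions)
    hits = evaluated = excluded = 0
    for mol_id, preds in groups.items():
        som = labels.get(mol_id) or frozenset()
        if not som:
            excluded += 1
            continue
        evaluated += 1
        top = {p.atom_idx for p in preds if p.rank <= 2}
        if som & top:
            hits += 1
    if evaluated == 0:
        raise EvaluationError("no molecule with annotated SOMs to evaluate")
    return hits / evaluated, evaluated, excluded


def evaluate_predictions(
    predictions: Sequence[SomPrediction],
    labels: dict[str, frozenset[int]],
    threshold: float,
) -> MetricsReport:
    """Full report: atom metrics over every atom, TOP-2 over annotated molecules.

    Molecules without annotations enter the atom-level metrics as
    all-negative and are excluded from TOP-2.
    """
    y_true = [
        int(p.atom_idx in (labels.get(p.mol_id) or frozenset()))
        for p in predictions
    ]
    y_score = [p.probability for p in predictions]
    report = atom_metrics(y_true, y_score, threshold)
    rate, n_eval, n_excl = top2_correctness(predictions, labels)
    report.top2 = rate
    report.n_molecules = n_eval
    report.n_top2_excluded = n_excl
    return report


@dataclass
class ReliabilityCorrelationReport:
    spearman_rho: float
    spearman_p: float
    defined: bool
    bins: pd.DataFrame  # per-quantile-bin accuracy/MCC for each metric


def reliability_correlation(
    fame_scores: Sequence[float],
    entropies: Sequence[float],
    correct: Sequence[bool],
    y_true: Optional[Sequence[int]] = None,
    y_pred: Optional[Sequence[int]] = None,
    n_bins: int = 5,
) -> ReliabilityCorrelationReport:
    """Compare the two reliability metrics against realized correctness.

    Reports the Spearman rank correlation between FAME score and entropy
    and, for each metric, accuracy (and MCC when labels and calls are
    supplied) within quantile bins, low to high metric value.  A constant
    metric vector makes the correlation undefined; it is then flagged
    rather than reported as a number.
    """
    fs = np.asarray(fame_scores, dtype=float)
    en = np.asarray(entropies, dtype=float)
    ok = np.asarray(correct, dtype=bool)
    if not (fs.size == en.size == ok.size):
        raise EvaluationError("reliability vectors must be aligned")
    if fs.size == 0:
        raise EvaluationError("empty reliability vectors")
    yt = np.asarray(y_true, dtype=int) if y_true is not None else None
    yp = np.asarray(y_pred, dtype=int) if y_pred is not None else None
    constant = np.all(fs == fs[0]) or np.all(en == en[0])
    if constant:
        log.warning("constant reliability vector: rank correlation undefined")
        rho, p = float("nan"), float("nan")
    else:
        rho, p = stats.spearmanr(fs, en)
    rows = []
    for name, values in (("fame_score", fs), ("shannon_entropy", en)):
        bin_ids = _quantile_bins(values, n_bins)
        for b in range(n_bins):
            mask = bin_ids == b
            if not mask.any():
                continue
            mcc = float("nan")
            if yt is not None and yp is not None:
                mcc = _safe_mcc(yt[mask], yp[mask])
            rows.append({
                "metric": name,
                "bin": b,
                "lo": float(values[mask].min()),
                "hi": float(values[mask].max()),
                "n": int(mask.sum()),
                "accuracy": float(ok[mask].mean()),
                "mcc": mcc,
            })
    bins = pd.DataFrame(rows)
    return ReliabilityCorrelationReport(
        spearman_rho=float(rho), spearman_p=float(p),
        defined=not constant, bins=bins,
    )


def _quantile_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    ranks = stats.rankdata(values, method="ordinal")
    return np.minimum((ranks - 1) * n_bins // len(values), n_bins - 1).astype(int)
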