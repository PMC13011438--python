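"""Prediction-reliability metrics.

Two complementary per-atom reliability measures accompany every prediction
when requested:

* the FAME applicability-domain score — the mean Tanimoto similarity
  between a query atom's binary fingerprint and its k nearest neighbors
  in the training-atom fingerprint set (k = 3 by default).  High values
  mean the atom's environment is well represented in the training data.
* the Shannon entropy of the predicted probability,
  H = -(p log2 p + (1-p) log2 (1-p)), in [0, 1]; low values mean a
  confident (near-0 or near-1) probability.

The FAME score is always computed on the binary block fingerprint, even
when the classifier was trained on count fingerprints: the Tanimoto
similarity is defined on bit vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .chem_core import SomkitError
from .fingerprints import FameBinaryFingerprint

log = logging.getLogger(__name__)


class ReliabilityError(SomkitError):
    pass


@dataclass(frozen=True)
class ReliabilityConfig:
    k: int = 3

    def __post_init__(self):
        if self.k < 1:
            raise ReliabilityError("k must be >= 1")


@dataclass(frozen=True)
class ReliabilityScores:
    fame_score: float
    shannon_entropy: float


def tanimoto(a, b) -> float:
    """Tanimoto similarity |a & b| / |a | b| between two bit vectors.

    Accepts :class:`FameBinaryFingerprint` or raw 0/1 arrays.  Two all-zero
    vectors have similarity 0.0 by convention.
    """
    va, vb = _bits(a), _bits(b)
    if va.shape != vb.shape:
        raise ReliabilityError(
            f"fingerprint schema mismatch: lengths {va.size} vs {vb.size}"
        )
    inter = int(np.dot(va, vb))
    union = int(va.sum()) + int(vb.sum()) - inter
    return inter / union if union else 0.0


def _bits(x) -> np.ndarray:
    if isinstance(x, FameBinaryFingerprint):
        return x.bits.astype(np.int64)
    return np.asarray(x, dtype=np.int64)


def bulk_tanimoto(query: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Tanimoto of one query bit vector against each row of a bit matrix."""
    q = query.astype(np.int64)
    ref = reference.astype(np.int64)
    inter = ref @ q
    union = ref.sum(axis=1) + q.sum() - inter
    with np.errstate(invalid="ignore"):
        sims = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return sims


def fame_score(
    query,
    reference_set,
    cfg: ReliabilityConfig = ReliabilityConfig(),
    return_neighbors: bool = False,
):
    """Mean Tanimoto similarity to the k most similar reference fingerprints.

    Ties at the k-th rank are broken by ascending reference index, which
    fixes the reported neighbor identities; the score itself is invariant
    to any tie-consistent selection because it averages similarity values.
    """
    q = _bits(query)
    ref = _reference_matrix(reference_set)
    if ref.shape[0] < cfg.k:
        raise ReliabilityError(
            f"reference set of size {ref.shape[0]} smaller than k={cfg.k}"
        )
    if ref.shape[1] != q.size:
        raise ReliabilityError(
            f"fingerprint schema mismatch: query length {q.size}, "
            f"reference length {ref.shape[1]}"
        )
    if q.sum() == 0:
        log.warning("all-zero query fingerprint: out of domain, FAME score 0")
        return (0.0, []) if return_neighbors else 0.0
    sims = bulk_tanimoto(q, ref)
    order = np.lexsort((np.arange(sims.size), -sims))
    top = order[: cfg.k]
    score = float(sims[top].mean())
    if return_neighbors:
        return score, [int(i) for i in top]
    return score


def fame_scores_matrix(
    queries: np.ndarray,
    reference: np.ndarray,
    cfg: ReliabilityConfig = ReliabilityConfig(),
) -> np.ndarray:
    """FAME scores for many query fingerprints at once.

    Equivalent to calling :func:`fame_score` per row (the score averages
    the k largest similarity values, so any tie-consistent selection
    agrees), but uses one BLAS matrix product instead of a Python loop.
    Intersections are exact: counts fit float32 integers.
    """
    if reference.shape[0] < cfg.k:
        raise ReliabilityError(
            f"reference set of size {reference.shape[0]} smaller than k={cfg.k}"
        )
    if queries.shape[1] != reference.shape[1]:
        raise ReliabilityError(
            f"fingerprint schema mismatch: query length {queries.shape[1]}, "
            f"reference length {reference.shape[1]}"
        )
    Q = queries.astype(np.float32)
    R = reference.astype(np.float32)
    inter = (Q @ R.T).astype(np.float64)
    qsum = Q.sum(axis=1).astype(np.float64)
    rsum = R.sum(axis=1).astype(np.float64)
    union = qsum[:, None] + rsum[None, :] - inter
    sims = np.where(union > 0, inter / np.maximum(union, 1.0), 0.0)
    top = -np.partition(-sims, cfg.k - 1, axis=1)[:, : cfg.k]
    scores = top.mean(axis=1)
    empty = qsum == 0
    if empty.any():
        log.warning("%d all-zero query fingerprints: out of domain, FAME score 0",
                    int(empty.sum()))
        scores[empty] = 0.0
    return scores


def _reference_matrix(reference_set) -> np.ndarray:
    if isinstance(reference_set, np.ndarray):
        return reference_set.astype(np.int64)
    rows = [_bits(fp) for fp in reference_set]
    return np.vstack(rows)


def shannon_entropy(p: float) -> float:
    """Binary Shannon entropy of a predicted probability, in bits."""
    if not 0.0 <= p <= 1.0:
        raise ReliabilityError(f"probability {p} outside [0, 1]")
    if p == 0.0 or p == 1.0:
        return 0.0
    return float(-(p * np.log2(p) + (1.0 - p) * np.log2(1.0 - p)))
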