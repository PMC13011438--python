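"""Metric suite against independent brute-force oracles."""

import numpy as np
import pytest

from somkit.evaluation import (
    EvaluationError,
    atom_metrics,
    reliability_correlation,
    top2_correctness,
)
from somkit.som_model import SomPrediction, rank_probabilities


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation under test)
# ---------------------------------------------------------------------------

def oracle_roc_auc(y, s):
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def oracle_average_precision(y, s):
    # step-wise average precision: sum over descending score thresholds of
    # (recall step) * precision, tied scores forming one step
    n_pos = sum(y)
    tp = fp = 0
    ap = 0.0
    prev_recall = 0.0
    for t in sorted(set(s), reverse=True):
        tp += sum(1 for yi, si in zip(y, s) if si == t and yi == 1)
        fp += sum(1 for yi, si in zip(y, s) if si == t and yi == 0)
        recall = tp / n_pos
        ap += (recall - prev_recall) * (tp / (tp + fp))
        prev_recall = recall
    return ap


def oracle_mcc(tp, tn, fp, fn):
    num = tp * tn - fp * fn
    den = ((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)) ** 0.5
    return num / den if den else 0.0


def _preds_from_scores(mol_id, scores):
    ranks = rank_probabilities(scores)
    return [
        SomPrediction(mol_id, i, "C", float(p), p >= 0.3, ranks[i])
        for i, p in enumerate(scores)
    ]


class TestAtomMetrics:
    def test_perfect_separation(self):
        rep = atom_metrics([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9], 0.3)
        assert rep.roc_auc == 1.0
        assert rep.pr_auc == 1.0

    def test_fixed_confusion_matrix_values(self):
        # TP=6, TN=2, FP=1, FN=1 at threshold 0.5
        y = [1] * 6 + [0] * 2 + [0] + [1]
        s = [0.9] * 6 + [0.1] * 2 + [0.8] + [0.2]
        rep = atom_metrics(y, s, 0.5)
        assert rep.mcc == pytest.approx(11 / 21, abs=1e-12)
        assert rep.precision == pytest.approx(6 / 7)
        assert rep.recall == pytest.approx(6 / 7)
        assert rep.mcc == pytest.approx(oracle_mcc(6, 2, 1, 1), abs=1e-12)

    def test_all_tied_scores_give_half_auc(self):
        rep = atom_metrics([0, 1, 0, 1], [0.4] * 4, 0.3)
        assert rep.roc_auc == pytest.approx(0.5)

    def test_single_class_flags_rank_metrics_undefined(self):
        rep = atom_metrics([1, 1, 1], [0.2, 0.6, 0.9], 0.3)
        assert not rep.rank_metrics_defined
        assert np.isnan(rep.roc_auc)
        assert rep.recall == pytest.approx(2 / 3)

    def test_matches_brute_force_oracles_on_random_instances(self):
        rng = np.random.default_rng(17)
        for trial in range(200):
            n = int(rng.integers(5, 50))
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                y[0], y[1] = 0, 1
            if trial % 3 == 0:
                s = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # forced ties
            else:
                s = rng.random(n)
            rep = atom_metrics(y.tolist(), s.tolist(), 0.5)
            assert rep.roc_auc == pytest.approx(
                oracle_roc_auc(y, s), abs=1e-12
            )
            assert rep.pr_auc == pytest.approx(
                oracle_average_precision(y.tolist(), s.tolist()), abs=1e-12
            )
            tp = int(((s >= 0.5) & (y == 1)).sum())
            tn = int(((s < 0.5) & (y == 0)).sum())
            fp = int(((s >= 0.5) & (y == 0)).sum())
            fn = int(((s < 0.5) & (y == 1)).sum())
            assert rep.mcc == pytest.approx(oracle_mcc(tp, tn, fp, fn), abs=1e-9)


class TestTop2:
    def test_som_ranked_first(self):
        preds = _preds_from_scores("m1", [0.9, 0.1, 0.2])
        rate, n, _ = top2_correctness(preds, {"m1": frozenset({0})})
        assert (rate, n) == (1.0, 1)

    def test_som_ranked_third_misses(self):
        preds = _preds_from_scores("m1", [0.9, 0.8, 0.2])
        rate, _, _ = top2_correctness(preds, {"m1": frozenset({2})})
        assert rate == 0.0

    def test_one_hit_one_miss(self):
        preds = _preds_from_scores("m1", [0.2, 0.9, 0.4]) + \
            _preds_from_scores("m2", [0.9, 0.8, 0.1])
        labels = {"m1": frozenset({2}), "m2": frozenset({2})}
        assert top2_correctness(preds, labels)[0] == 0.5

    def test_unannotated_molecules_excluded_and_counted(self):
        preds = _preds_from_scores("m1", [0.9, 0.1]) + \
            _preds_from_scores("m2", [0.5, 0.6])
        rate, n_eval, n_excl = top2_correctness(preds, {"m1": frozenset({0})})
        assert (rate, n_eval, n_excl) == (1.0, 1, 1)

    def test_single_atom_molecule_is_its_own_top2(self):
        preds = _preds_from_scores("m1", [0.4])
        assert top2_correctness(preds, {"m1": frozenset({0})})[0] == 1.0

    def test_matches_exhaustive_verification_on_random_fixtures(self):
        rng = np.random.default_rng(29)
        for _ in range(200):
            n_mols = int(rng.integers(1, 8))
            preds, labels, expected_hits = [], {}, 0
            for m in range(n_mols):
                n = int(rng.integers(1, 9))
                scores = rng.random(n).round(2)  # rounded -> occasional ties
                mol_id = f"m{m}"
                preds += _preds_from_scores(mol_id, scores.tolist())
                som = frozenset(
                    int(i) for i in rng.choice(n, size=rng.integers(1, n + 1),
                                               replace=False)
                )
                labels[mol_id] = som
                order = sorted(range(n), key=lambda i: (-scores[i], i))
                if som & set(order[:2]):
                    expected_hits += 1
            rate, n_eval, _ = top2_correctness(preds, labels)
            assert n_eval == n_mols
            assert rate == pytest.approx(expected_hits / n_mols)

    def test_atom_permutation_changes_no_metric(self):
        rng = np.random.default_rng(3)
        scores = rng.random(7)
        y = rng.integers(0, 2, size=7)
        y[0], y[1] = 1, 0
        rep1 = atom_metrics(y.tolist(), scores.tolist(), 0.3)
        perm = rng.permutation(7)
        rep2 = atom_metrics(y[perm].tolist(), scores[perm].tolist(), 0.3)
        for f in ("roc_auc", "pr_auc", "f1", "mcc", "precision", "recall"):
            assert getattr(rep1, f) == pytest.approx(getattr(rep2, f), abs=1e-12)


class TestReliabilityCorrelation:
    def test_monotone_transform_gives_perfect_anticorrelation(self):
        fs = np.linspace(0.1, 0.9, 50)
        entropies = 1.0 - fs ** 2  # monotone decreasing in fs
        rep = reliability_correlation(fs, entropies, [True] * 50)
        assert rep.spearman_rho == pytest.approx(-1.0)

    def test_independent_vectors_near_zero_correlation(self):
        rng = np.random.default_rng(101)
        fs, en = rng.random(1000), rng.random(1000)
        rep = reliability_correlation(fs, en, rng.random(1000) > 0.5)
        assert abs(rep.spearman_rho) < 0.1

    def test_constant_vector_flagged_undefined(self):
        rep = reliability_correlation([0.5] * 10, list(np.linspace(0, 1, 10)),
                                      [True] * 10)
        assert not rep.defined
        assert np.isnan(rep.spearman_rho)

    def test_binned_table_covers_all_points(self):
        rng = np.random.default_rng(5)
        n = 200
        rep = reliability_correlation(
            rng.random(n), rng.random(n), rng.random(n) > 0.3,
            y_true=rng.integers(0, 2, n), y_pred=rng.integers(0, 2, n),
        )
        per_metric = rep.bins.groupby("metric")["n"].sum()
        assert (per_metric == n).all()
        assert rep.bins["accuracy"].between(0, 1).all()

    def test_misaligned_vectors_rejected(self):
        with pytest.raises(EvaluationError):
            reliability_correlation([0.1], [0.2, 0.3], [True])
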