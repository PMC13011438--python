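"""Random-forest SOM model: training, prediction, ranking, serialization."""

import numpy as np
import pytest

import somkit
from somkit import fixtures as fx
from somkit.features import FeaturizationError, build_feature_table
from somkit.som_model import (
    ModelError,
    TrainingConfig,
    load_model,
    predict,
    rank_probabilities,
    save_model,
    train,
)


class TestTrainingContract:
    def test_same_seed_reproduces_identical_probabilities(self, small_fixture_set):
        train_m, test_m = fx.split(small_fixture_set, (0.8, 0.2), seed=2)
        cfg = TrainingConfig(n_trees=30, seed=9)
        p1 = [p.probability for p in predict(train(train_m, cfg), test_m)]
        p2 = [p.probability for p in predict(train(train_m, cfg), test_m)]
        assert p1 == p2

    def test_single_class_data_rejected(self, small_fixture_set):
        mols = [m for m in small_fixture_set if m.som_labels][:5]
        all_pos = []
        for m in mols:
            m2 = somkit.MoleculeRecord(
                mol_id=m.mol_id, atoms=m.atoms, bonds=m.bonds,
                som_labels=frozenset(range(m.n_atoms)), rdmol=m.rdmol,
            )
            all_pos.append(m2)
        with pytest.raises(ModelError, match="single class"):
            train(all_pos, TrainingConfig(n_trees=5))

    def test_unlabeled_molecules_excluded(self, small_fixture_set):
        unlabeled = somkit.perceive_molecule("CCCCCCC", "heptane")
        model = train(
            list(small_fixture_set[:30]) + [unlabeled],
            TrainingConfig(n_trees=10, seed=0),
        )
        n_labeled_atoms = sum(
            m.n_atoms for m in small_fixture_set[:30] if m.som_labels
        )
        assert model.reference_matrix().shape[0] == n_labeled_atoms

    def test_feature_table_training_path(self, small_fixture_set):
        cfg = TrainingConfig(n_trees=10, seed=1)
        table = build_feature_table(
            [m for m in small_fixture_set[:30] if m.som_labels],
            cfg.featurization(),
        )
        model = train(table, cfg)
        with pytest.raises(ModelError, match="reference fingerprints"):
            model.reference_matrix()


class TestPrediction:
    def test_ranking_is_permutation_consistent_with_probabilities(
        self, tiny_model, small_fixture_set
    ):
        preds = predict(tiny_model, small_fixture_set[:10])
        by_mol = {}
        for p in preds:
            by_mol.setdefault(p.mol_id, []).append(p)
        for group in by_mol.values():
            ranks = sorted(p.rank for p in group)
            assert ranks == list(range(1, len(group) + 1))
            ordered = sorted(group, key=lambda p: p.rank)
            for a, b in zip(ordered, ordered[1:]):
                assert a.probability >= b.probability
                assert all(0.0 <= p.probability <= 1.0 for p in group)

    def test_ranking_complete_even_when_no_positive_calls(self):
        probs = [0.05, 0.1, 0.02]
        assert rank_probabilities(probs) == [2, 1, 3]

    def test_probability_exactly_at_threshold_is_called_positive(
        self, tiny_model, ethanol
    ):
        import dataclasses

        class _BoundaryForest:
            classes_ = np.array([0, 1])

            @staticmethod
            def predict_proba(X):
                return np.column_stack(
                    [np.full(len(X), 0.7), np.full(len(X), 0.3)]
                )

        assert tiny_model.config.threshold == 0.3
        stub = dataclasses.replace(tiny_model, forest=_BoundaryForest())
        preds = predict(stub, [ethanol])
        assert all(p.probability == 0.3 and p.call for p in preds)

    def test_rank_ties_broken_by_atom_index(self):
        assert rank_probabilities([0.5, 0.5, 0.9]) == [2, 3, 1]

    def test_molecule_order_invariance(self, tiny_model, small_fixture_set):
        mols = small_fixture_set[:8]
        fwd = {(p.mol_id, p.atom_idx): p.probability
               for p in predict(tiny_model, mols)}
        rev = {(p.mol_id, p.atom_idx): p.probability
               for p in predict(tiny_model, list(reversed(mols)))}
        assert fwd == rev

    def test_reliability_scores_attached_on_request(self, tiny_model,
                                                    small_fixture_set):
        preds = predict(tiny_model, small_fixture_set[:4], with_reliability=True)
        for p in preds:
            assert p.reliability is not None
            assert 0.0 <= p.reliability.fame_score <= 1.0
            assert 0.0 <= p.reliability.shannon_entropy <= 1.0
        plain = predict(tiny_model, small_fixture_set[:4])
        assert all(p.reliability is None for p in plain)


class TestSerialization:
    def test_save_load_roundtrip_preserves_predictions(
        self, tiny_model, small_fixture_set, tmp_path
    ):
        path = tmp_path / "model.bundle"
        save_model(tiny_model, str(path))
        loaded = load_model(str(path))
        mols = small_fixture_set[:6]
        before = [(p.mol_id, p.atom_idx, p.probability, p.rank)
                  for p in predict(tiny_model, mols, with_reliability=True)]
        after = [(p.mol_id, p.atom_idx, p.probability, p.rank)
                 for p in predict(loaded, mols, with_reliability=True)]
        assert before == after

    def test_identical_training_runs_serialize_identically(
        self, small_fixture_set, tmp_path
    ):
        cfg = TrainingConfig(n_trees=15, seed=4)
        a, b = tmp_path / "a.bundle", tmp_path / "b.bundle"
        save_model(train(small_fixture_set[:25], cfg), str(a))
        save_model(train(small_fixture_set[:25], cfg), str(b))
        assert a.read_bytes() == b.read_bytes()

    def test_corrupted_bundle_raises_integrity_error(self, tiny_model, tmp_path):
        path = tmp_path / "model.bundle"
        save_model(tiny_model, str(path))
        blob = bytearray(path.read_bytes())
        blob[len(blob) // 2] ^= 0xFF
        path.write_bytes(bytes(blob))
        with pytest.raises(ModelError):
            load_model(str(path))

    def test_not_a_bundle_rejected(self, tmp_path):
        path = tmp_path / "junk.bundle"
        path.write_bytes(b"not a model")
        with pytest.raises(ModelError):
            load_model(str(path))

    def test_reliability_without_reference_fingerprints_errors(
        self, small_fixture_set
    ):
        cfg = TrainingConfig(n_trees=5, seed=0)
        table = build_feature_table(
            [m for m in small_fixture_set[:20] if m.som_labels],
            cfg.featurization(),
        )
        model = train(table, cfg)
        with pytest.raises(ModelError, match="reference fingerprints"):
            predict(model, small_fixture_set[:2], with_reliability=True)


class TestThresholdSemantics:
    def test_config_validation(self):
        with pytest.raises(ModelError):
            TrainingConfig(threshold=0.0)
        with pytest.raises(ModelError):
            TrainingConfig(n_trees=0)

    def test_threshold_sweep_monotonicity(self, tiny_model, small_fixture_set):
        """On a fixed prediction set, raising the threshold cannot raise
        recall and (here) does not lower precision."""
        from somkit.evaluation import atom_metrics

        preds = predict(tiny_model, small_fixture_set[:40])
        labels = {m.mol_id: m.som_labels for m in small_fixture_set[:40]}
        y = [int(p.atom_idx in labels[p.mol_id]) for p in preds]
        s = [p.probability for p in preds]
        recalls, precisions = [], []
        for t in (0.1, 0.2, 0.3, 0.5, 0.7):
            rep = atom_metrics(y, s, t)
            recalls.append(rep.recall)
            precisions.append(rep.precision)
        assert all(a >= b for a, b in zip(recalls, recalls[1:]))
        assert all(a <= b for a, b in zip(precisions, precisions[1:]))
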