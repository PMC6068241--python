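"""Splitting, base-classifier training, weighted voting and evaluation."""

from __future__ import annotations

import numpy as np
import pytest

import wrsvmc as w
from wrsvmc.ensemble import BaseClassifier


class FixedVotes:
    """Stand-in decision function returning a preset vote sequence."""

    def __init__(self, votes):
        self.votes = np.asarray(votes, dtype=int)

    def predict(self, X):
        return self.votes[: np.atleast_2d(X).shape[0]]


def stub_ensemble(vote_rows, weights, majority_label=-1, mode="weighted"):
    """Ensemble whose classifier i always votes vote_rows[i]."""
    clfs = [
        BaseClassifier(
            feature_indices=np.array([0]),
            model=FixedVotes(votes),
            weight=float(wt),
            validation_accuracy=float(wt),
        )
        for votes, wt in zip(vote_rows, weights)
    ]
    cfg = w.SvmConfig(n_train_samples=2, n_features=1)
    return w.WrsvmcEnsemble(
        classifiers=clfs, mode=mode, config=cfg, rng_seed=0, majority_label=majority_label
    )


class TestSplitDataset:
    def test_sizes_and_partition(self, small_planted):
        _, dataset, _, _ = small_planted
        split = w.split_dataset(dataset, n_train_val=19, seed=3)
        assert split.train_val_indices.size == 19
        assert split.test_indices.size == dataset.n_samples - 19
        union = np.union1d(split.train_val_indices, split.test_indices)
        assert np.array_equal(union, np.arange(dataset.n_samples))
        for part in (split.train_val_indices, split.test_indices):
            assert set(np.unique(dataset.y[part])) == {-1, 1}

    def test_same_seed_gives_identical_split(self, small_planted):
        _, dataset, _, _ = small_planted
        a = w.split_dataset(dataset, 19, seed=11)
        b = w.split_dataset(dataset, 19, seed=11)
        assert np.array_equal(a.train_val_indices, b.train_val_indices)
        assert np.array_equal(a.test_indices, b.test_indices)

    def test_reference_split_sizes(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(198, 5))
        y = np.array([1] * 93 + [-1] * 105)
        ds = w.Dataset(X, y)
        split = w.split_dataset(ds, n_train_val=125, seed=0)
        assert split.test_indices.size == 73

    def test_impossible_class_coverage_errors(self):
        X = np.random.default_rng(1).normal(size=(6, 3))
        y = np.array([1, -1, -1, -1, -1, -1])
        with pytest.raises(ValueError):
            w.split_dataset(w.Dataset(X, y), n_train_val=3, seed=0)


class TestTrainBase:
    def test_perfectly_separable_data_gets_full_weight(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 0.1, (20, 4)) + 10, rng.normal(0, 0.1, (20, 4)) - 10])
        y = np.array([1] * 20 + [-1] * 20)
        ds = w.Dataset(X, y)
        split = w.split_dataset(ds, n_train_val=30, seed=1)
        cfg = w.SvmConfig(n_train_samples=10, n_features=3)
        clf = w.train_base(ds, split, cfg, seed=2)
        assert clf.weight == 1.0
        assert clf.validation_accuracy == 1.0

    def test_weight_floor_is_zero_and_subset_sizes_hold(self, small_planted):
        _, dataset, split, config = small_planted
        clf = w.train_base(dataset, split, config, seed=9)
        assert 0.0 <= clf.weight <= 1.0
        assert clf.feature_indices.size == config.n_features
        assert np.array_equal(clf.feature_indices, np.sort(clf.feature_indices))
        assert clf.sample_indices.size == config.n_train_samples

    def test_no_validation_remainder_errors(self, small_planted):
        _, dataset, split, _ = small_planted
        cfg = w.SvmConfig(n_train_samples=19, n_features=5)
        with pytest.raises(ValueError, match="validation"):
            w.train_base(dataset, split, cfg, seed=0)


class TestVoting:
    def test_weighted_vote_arithmetic(self):
        ens = stub_ensemble([[1], [1], [-1]], [0.9, 0.6, 0.55])
        X = np.zeros((1, 1))
        s_plus, s_minus = w.vote_scores(ens, X)
        assert s_plus[0] == pytest.approx(1.5)
        assert s_minus[0] == pytest.approx(0.55)
        assert w.predict_one(ens, X[0]) == 1

    def test_tie_breaks_to_majority_class(self):
        ens = stub_ensemble([[1], [-1]], [0.5, 0.5], majority_label=-1)
        assert w.predict_one(ens, np.zeros(1)) == -1
        ens = stub_ensemble([[1], [-1]], [0.5, 0.5], majority_label=1)
        assert w.predict_one(ens, np.zeros(1)) == 1

    def test_score_conservation(self, rng):
        # S+ + S- equals the total weight mass for every sample
        n_clf, n_samples = 17, 40
        votes = rng.choice([-1, 1], size=(n_clf, n_samples))
        weights = rng.uniform(0, 1, size=n_clf)
        ens = stub_ensemble(list(votes), weights)
        s_plus, s_minus = w.vote_scores(ens, np.zeros((n_samples, 1)))
        assert np.allclose(s_plus + s_minus, weights.sum())

    def test_equal_weight_mode_is_majority_vote(self, rng):
        for _ in range(50):
            n_clf = int(rng.integers(1, 15))
            votes = rng.choice([-1, 1], size=(n_clf, 8))
            ens = stub_ensemble(list(votes), np.ones(n_clf), majority_label=-1)
            pred = w.predict(ens, np.zeros((8, 1)))
            sums = votes.sum(axis=0)
            expected = np.where(sums > 0, 1, np.where(sums < 0, -1, -1))
            assert np.array_equal(pred, expected)

    def test_prediction_invariant_to_classifier_order(self, rng):
        votes = rng.choice([-1, 1], size=(9, 12))
        weights = rng.uniform(0, 1, size=9)
        ens = stub_ensemble(list(votes), weights)
        perm = rng.permutation(9)
        ens_p = stub_ensemble(list(votes[perm]), weights[perm])
        X = np.zeros((12, 1))
        assert np.array_equal(w.predict(ens, X), w.predict(ens_p, X))

    def test_dimension_mismatch_rejected(self, small_planted):
        _, dataset, split, config = small_planted
        ens = w.train_ensemble(dataset, split, config, n_classifiers=3, seed=0)
        with pytest.raises(ValueError, match="dimension"):
            w.predict(ens, np.zeros((2, 3)))


class TestTrainEnsemble:
    def test_reproducible_weights(self, small_planted):
        _, dataset, split, config = small_planted
        a = w.train_ensemble(dataset, split, config, n_classifiers=8, seed=4)
        b = w.train_ensemble(dataset, split, config, n_classifiers=8, seed=4)
        assert np.array_equal(a.weights, b.weights)
        for ca, cb in zip(a.classifiers, b.classifiers):
            assert np.array_equal(ca.feature_indices, cb.feature_indices)

    def test_prefix_stability(self, small_planted):
        _, dataset, split, config = small_planted
        big = w.train_ensemble(dataset, split, config, n_classifiers=6, seed=4)
        small = w.train_ensemble(dataset, split, config, n_classifiers=3, seed=4)
        assert np.array_equal(big.weights[:3], small.weights)

    def test_single_classifier_ensemble_equals_base(self, small_planted):
        _, dataset, split, config = small_planted
        ens = w.train_ensemble(dataset, split, config, n_classifiers=1, seed=2)
        X_te = dataset.X[split.test_indices]
        assert np.array_equal(w.predict(ens, X_te), ens.classifiers[0].predict(X_te))

    def test_equal_mode_sets_unit_weights(self, small_planted):
        _, dataset, split, config = small_planted
        ens = w.train_ensemble(dataset, split, config, n_classifiers=5, mode="equal", seed=1)
        assert (ens.weights == 1.0).all()
        assert any(c.validation_accuracy != 1.0 for c in ens.classifiers)


class TestEvaluation:
    def test_accuracy_ratio(self):
        res = w.EvaluationResult.from_counts(tp=33, fn=3, tn=31, fp=6)
        assert res.t == 73 and res.t_true == 64
        assert res.p_true == pytest.approx(64 / 73)
        assert res.sensitivity == pytest.approx(33 / 36)
        assert res.specificity == pytest.approx(31 / 37)

    def test_all_wrong_gives_zero(self):
        y = np.array([1, 1, -1, -1])
        res = w.EvaluationResult.from_predictions(y, -y)
        assert res.p_true == 0.0

    def test_evaluate_matches_manual_confusion(self, small_planted):
        _, dataset, split, config = small_planted
        ens = w.train_ensemble(dataset, split, config, n_classifiers=10, seed=3)
        X_te, y_te = dataset.X[split.test_indices], dataset.y[split.test_indices]
        res = w.evaluate(ens, X_te, y_te)
        pred = w.predict(ens, X_te)
        assert res.t_true == int((pred == y_te).sum())
        assert res.tp + res.fn + res.tn + res.fp == y_te.size


class TestSizeSweep:
    def test_grid_arithmetic(self, small_planted):
        _, dataset, split, config = small_planted
        sizes = list(range(2, 21, 2))
        res = w.sweep_ensemble_size(dataset, split, config, sizes=sizes, seed=5)
        assert len(res.table) == len(sizes)
        assert res.optimal_size in sizes

    def test_prefix_reuse_matches_fresh_training(self, small_planted):
        _, dataset, split, config = small_planted
        res = w.sweep_ensemble_size(dataset, split, config, sizes=[3, 6], seed=5)
        fresh = w.train_ensemble(dataset, split, config, n_classifiers=3, seed=5)
        X_te, y_te = dataset.X[split.test_indices], dataset.y[split.test_indices]
        acc3 = w.evaluate(fresh, X_te, y_te).p_true
        assert res.table.set_index("size").loc[3, "accuracy"] == pytest.approx(acc3)

    def test_singleton_grid_equals_single_classifier(self, small_planted):
        _, dataset, split, config = small_planted
        res = w.sweep_ensemble_size(dataset, split, config, sizes=[1], seed=6)
        single = w.train_ensemble(dataset, split, config, n_classifiers=1, seed=6)
        X_te, y_te = dataset.X[split.test_indices], dataset.y[split.test_indices]
        assert res.table["accuracy"][0] == pytest.approx(w.evaluate(single, X_te, y_te).p_true)


class TestSerialization:
    def test_roundtrip_preserves_predictions(self, small_planted, tmp_path):
        _, dataset, split, config = small_planted
        ens = w.train_ensemble(dataset, split, config, n_classifiers=5, seed=8)
        path = tmp_path / "model.json"
        w.save_ensemble(ens, path)
        back = w.load_ensemble(path)
        X_te = dataset.X[split.test_indices]
        assert np.array_equal(w.predict(ens, X_te), w.predict(back, X_te))
        assert np.allclose(back.weights, ens.weights)
        assert back.config.sigma == ens.config.sigma
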