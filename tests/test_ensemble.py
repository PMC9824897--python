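"""Base classifiers and fusion: closed forms, oracles, invariants."""

import numpy as np
import pytest

import hybridseek as hs
from hybridseek.ensemble import best_split, _fit_stump
from hybridseek.errors import ParameterError, TrainingError


class TestWeightedError:
    def test_all_correct_zero(self):
        assert hs.weighted_error([1, -1, 1], [1, -1, 1], [0.5, 0.25, 0.25]) == 0.0

    def test_uniform_weights_count(self):
        err = hs.weighted_error([1, 1, 1, 1], [1, 1, 1, -1], [0.25] * 4)
        assert err == pytest.approx(0.25)

    def test_weighted_single_mistake(self):
        err = hs.weighted_error(
            [-1, 1, 1, 1], [1, 1, 1, 1], [0.7, 0.1, 0.1, 0.1]
        )
        assert err == pytest.approx(0.7)

    def test_unnormalized_weights_rejected(self):
        with pytest.raises(ParameterError):
            hs.weighted_error([1], [1], [0.5])


class TestLearnerWeight:
    def test_chance_learner_zero_weight(self):
        assert hs.learner_weight(0.5) == 0.0

    def test_closed_form(self):
        assert hs.learner_weight(0.1) == pytest.approx(0.5 * np.log(9), abs=1e-9)
        assert hs.learner_weight(0.1) == pytest.approx(1.098612, abs=1e-6)

    def test_antisymmetry(self):
        assert hs.learner_weight(0.9) == pytest.approx(-hs.learner_weight(0.1))

    def test_extreme_errors_stay_finite(self):
        assert np.isfinite(hs.learner_weight(0.0))
        assert np.isfinite(hs.learner_weight(1.0))


class TestAdaBoost:
    def test_separable_single_round(self, separable_1d):
        X, y = separable_1d
        model = hs.adaboost_train(X, y, rounds=1)
        pred = (model.predict(X) > 0).astype(int)
        assert np.mean(pred == y) == 1.0

    def test_xor_needs_boosting(self):
        """Boosted stumps beat the 0.75 single-stump ceiling on XOR data."""
        rng = np.random.default_rng(7)
        X = rng.uniform(-1, 1, size=(200, 2))
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
        # brute-force oracle: no single stump beats ~0.75 accuracy on XOR
        t = np.where(y == 1, 1, -1)
        w = np.full(len(y), 1 / len(y))
        _, phi = _fit_stump(X, t, w)
        assert phi >= 0.25 - 1e-9
        model = hs.adaboost_train(X, y, rounds=300)
        pred = (model.predict(X) > 0).astype(int)
        assert np.mean(pred == y) > 1.0 - phi

    def test_sample_weights_renormalized_each_round(self, separable_1d):
        # indirectly: training runs many rounds without weight blow-up and
        # scores stay within [0, 1]
        X, y = separable_1d
        model = hs.adaboost_train(X, y, rounds=10)
        s = model.score(X)
        assert np.all((s >= 0) & (s <= 1))

    def test_first_stump_beats_chance(self, planted_dataset):
        X, y, _ = planted_dataset
        model = hs.adaboost_train(X[:200], y[:200], rounds=15)
        t = np.where(y[:200] == 1, 1, -1)
        w = np.full(200, 1 / 200)
        first_err = hs.weighted_error(model.learners[0].predict(X[:200]), t, w)
        assert first_err < 0.5

    def test_single_class_rejected(self):
        with pytest.raises(TrainingError):
            hs.adaboost_train(np.zeros((4, 2)), np.ones(4), rounds=3)


class TestGini:
    @pytest.mark.parametrize(
        "props, expected",
        [((1.0,), 0.0), ((0.5, 0.5), 0.5), ((0.7, 0.3), 0.42)],
    )
    def test_values(self, props, expected):
        assert hs.gini_impurity(props) == pytest.approx(expected)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ParameterError):
            hs.gini_impurity((0.7, 0.7))


class TestDecisionTree:
    def test_threshold_separable_is_depth_one(self, separable_1d):
        X, y = separable_1d
        model = hs.dt_train(X, y)
        assert np.mean(model.predict(X) == y) == 1.0
        assert model.root.feature == 0
        assert model.root.left.is_leaf and model.root.right.is_leaf

    def test_pure_input_single_leaf(self):
        model = hs.dt_train(np.arange(8).reshape(4, 2), np.ones(4, int))
        assert model.root.is_leaf
        assert model.root.distribution[1] == 1.0

    def test_conflicting_duplicates_no_recursion(self):
        X = np.ones((6, 2))
        y = np.array([0, 1, 0, 1, 1, 1])
        model = hs.dt_train(X, y)
        assert model.root.is_leaf
        assert model.root.distribution[1] == pytest.approx(4 / 6)

    def test_first_split_matches_exhaustive_oracle(self):
        """On tiny inputs the greedy split equals the exhaustive optimum."""
        rng = np.random.default_rng(21)
        for _ in range(25):
            n = int(rng.integers(4, 13))
            d = int(rng.integers(1, 4))
            X = rng.normal(size=(n, d))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue

            def gini(labels):
                if len(labels) == 0:
                    return 0.0
                p = np.mean(labels)
                return 1 - p**2 - (1 - p) ** 2

            best_gain, best_jt = 0.0, None
            parent = gini(y)
            for j in range(d):
                for t in np.unique(X[:, j])[:-1]:
                    mask = X[:, j] <= t
                    gain = (
                        parent
                        - mask.mean() * gini(y[mask])
                        - (1 - mask.mean()) * gini(y[~mask])
                    )
                    if gain > best_gain + 1e-12:
                        best_gain, best_jt = gain, j
            split = best_split(X, y)
            if best_jt is None:
                assert split is None or split[2] <= 1e-12
            else:
                assert split is not None
                assert split[2] == pytest.approx(best_gain, abs=1e-12)
                assert split[0] == best_jt


class TestRandomForest:
    def test_determinism(self, planted_dataset):
        X, y, _ = planted_dataset
        a = hs.rf_train(X[:200], y[:200], n_trees=20, seed=5)
        b = hs.rf_train(X[:200], y[:200], n_trees=20, seed=5)
        assert np.array_equal(a.predict(X[200:]), b.predict(X[200:]))

    def test_heldout_accuracy_on_planted_signal(self, planted_dataset):
        X, y, _ = planted_dataset
        model = hs.rf_train(X[:300], y[:300], n_trees=50, seed=1)
        assert np.mean(model.predict(X[300:]) == y[300:]) >= 0.9

    def test_single_tree_no_bootstrap(self, planted_dataset):
        X, y, _ = planted_dataset
        model = hs.rf_train(
            X[:100], y[:100], n_trees=1, n_sub_features=X.shape[1] - 1,
            seed=0, bootstrap=False,
        )
        assert np.mean(model.predict(X[:100]) == y[:100]) >= 0.95

    def test_feature_subset_must_be_smaller(self, planted_dataset):
        X, y, _ = planted_dataset
        with pytest.raises(ParameterError):
            hs.rf_train(X, y, n_sub_features=X.shape[1], seed=0)


@pytest.fixture(scope="module")
def trained(planted_dataset):
    X, y, _ = planted_dataset
    ab = hs.adaboost_train(X[:300], y[:300], rounds=10)
    rf = hs.rf_train(X[:300], y[:300], n_trees=20, seed=0)
    dt = hs.dt_train(X[:300], y[:300], max_depth=4)
    return X[300:], y[300:], ab, rf, dt


class TestFusion:
    def test_degenerate_fusion_equals_adaboost(self, trained):
        X_te, _, ab, rf, dt = trained
        model = hs.EnsembleModel(ab, rf, dt, (1.0, 0.0, 0.0))
        fused, _ = hs.fuse_predict(model, X_te)
        np.testing.assert_allclose(fused, ab.score(X_te), rtol=1e-12)

    def test_equal_weights_average(self, trained):
        X_te, _, ab, rf, dt = trained
        model = hs.EnsembleModel(ab, rf, dt, (1 / 3, 1 / 3, 1 / 3))
        fused, _ = hs.fuse_predict(model, X_te)
        mean = model.base_scores(X_te).mean(axis=1)
        np.testing.assert_allclose(fused, mean, rtol=1e-12)

    def test_hand_weighted_sum(self):
        # base scores (0.9, 0.2, 0.6), weights (0.5, 0.3, 0.2) -> 0.63
        assert np.dot([0.9, 0.2, 0.6], [0.5, 0.3, 0.2]) == pytest.approx(0.63)

    def test_convex_combination_bounds(self, trained):
        X_te, _, ab, rf, dt = trained
        model = hs.EnsembleModel(ab, rf, dt, (0.2, 0.5, 0.3))
        fused, _ = hs.fuse_predict(model, X_te)
        scores = model.base_scores(X_te)
        assert np.all(fused >= scores.min(axis=1) - 1e-12)
        assert np.all(fused <= scores.max(axis=1) + 1e-12)

    def test_off_simplex_weights_rejected(self, trained):
        _, _, ab, rf, dt = trained
        with pytest.raises(ParameterError):
            hs.EnsembleModel(ab, rf, dt, (0.5, 0.5, 0.5))

    def test_archive_round_trip(self, trained, tmp_path):
        X_te, _, ab, rf, dt = trained
        model = hs.EnsembleModel(ab, rf, dt, (0.4, 0.4, 0.2))
        path = tmp_path / "model.pkl"
        model.save(path)
        back = hs.EnsembleModel.load(path)
        f1, _ = hs.fuse_predict(model, X_te)
        f2, _ = hs.fuse_predict(back, X_te)
        np.testing.assert_array_equal(f1, f2)

    def test_bad_archive_rejected(self, tmp_path):
        import pickle

        path = tmp_path / "bogus.pkl"
        with open(path, "wb") as fh:
            pickle.dump({"version": "other"}, fh)
        with pytest.raises(ParameterError):
            hs.EnsembleModel.load(path)
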