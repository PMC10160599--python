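"""SVM classification: splitting, fitting, prediction, grid search."""

import numpy as np
import pytest

from wavebeat.classify import (GridSpec, RbfSvmClassifier, SVMConfig, fit_svm,
                               grid_search_cv, predict, stratified_split)
from wavebeat.errors import SchemaError
from wavebeat.features import FeatureMatrix


def _clusters(n_per_class, separation, rng, n_features=2):
    X = np.vstack([
        rng.normal(0.0, 1.0, size=(n_per_class, n_features)),
        rng.normal(separation, 1.0, size=(n_per_class, n_features)),
    ])
    y = np.repeat([0, 1], n_per_class)
    return FeatureMatrix(X, y)


class TestStratifiedSplit:
    def test_scaled_class_counts_preserved(self, rng):
        # 900 + 880 items at test_fraction 0.1 -> a 178-item test partition
        # carrying the 90/88 class balance of the reference test set
        X = rng.normal(size=(1780, 2))
        y = np.concatenate([np.zeros(900, int), np.ones(880, int)])
        fm = FeatureMatrix(X, y)
        train, test = stratified_split(fm, 0.1, seed=0)
        assert test.n_beats == 178
        assert int((test.y == 0).sum()) == 90
        assert int((test.y == 1).sum()) == 88

    def test_deterministic_per_seed(self, rng):
        fm = _clusters(50, 3.0, rng)
        a_train, a_test = stratified_split(fm, 0.3, seed=5)
        b_train, b_test = stratified_split(fm, 0.3, seed=5)
        np.testing.assert_array_equal(a_test.X, b_test.X)

    def test_half_split_on_balanced_20(self, rng):
        fm = _clusters(10, 3.0, rng)
        train, test = stratified_split(fm, 0.5, seed=0)
        for part in (train, test):
            assert int((part.y == 0).sum()) == 5
            assert int((part.y == 1).sum()) == 5

    def test_partitions_disjoint_and_exhaustive(self, rng):
        fm = _clusters(30, 3.0, rng)
        train, test = stratified_split(fm, 0.25, seed=1)
        stacked = np.vstack([train.X, test.X])
        assert stacked.shape[0] == fm.n_beats
        order = np.lexsort(stacked.T)
        base = np.lexsort(fm.X.T)
        np.testing.assert_array_equal(stacked[order], fm.X[base])

    def test_single_class_rejected(self, rng):
        fm = FeatureMatrix(rng.normal(size=(10, 2)), np.zeros(10, int))
        with pytest.raises(ValueError):
            stratified_split(fm, 0.5)

    def test_bad_fraction_rejected(self, rng):
        fm = _clusters(10, 3.0, rng)
        for frac in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                stratified_split(fm, frac)


class TestFitPredict:
    def test_separated_clusters_fit_near_perfectly(self, rng):
        fm = _clusters(100, 6.0, rng)
        model = fit_svm(fm, SVMConfig(C=1.0, gamma=0.1))
        assert np.mean(model.predict(fm.X) == fm.y) >= 0.99

    def test_xor_pattern_separable_with_rbf(self, rng):
        centers = np.array([[0, 0], [4, 4], [0, 4], [4, 0]])
        X = np.vstack([rng.normal(c, 0.3, size=(40, 2)) for c in centers])
        y = np.repeat([0, 0, 1, 1], 40)
        model = RbfSvmClassifier(C=10.0, gamma=1.0).fit(X, y)
        assert np.mean(model.predict(X) == y) >= 0.95

    def test_small_c_widens_margin(self, rng):
        fm = _clusters(60, 6.0, rng)
        loose = RbfSvmClassifier(C=0.01, gamma=0.1).fit(fm.X, fm.y)
        tight = RbfSvmClassifier(C=100.0, gamma=0.1).fit(fm.X, fm.y)
        assert len(loose.support_vectors_) >= len(tight.support_vectors_)

    def test_degenerate_identical_rows_rejected(self):
        X = np.ones((10, 3))
        y = np.repeat([0, 1], 5)
        with pytest.raises(ValueError, match="identical"):
            RbfSvmClassifier().fit(X, y)

    def test_too_few_items_per_class_rejected(self, rng):
        X = rng.normal(size=(3, 2))
        with pytest.raises(ValueError):
            RbfSvmClassifier().fit(X, np.array([0, 0, 1]))

    def test_predictions_survive_serialization(self, rng, tmp_path):
        fm = _clusters(50, 6.0, rng)
        model = fit_svm(fm, SVMConfig(C=1.0, gamma=0.1))
        labels, scores = predict(model, fm)
        path = model.save(tmp_path / "model.joblib")
        back = RbfSvmClassifier.load(path)
        labels2, scores2 = predict(back, fm)
        np.testing.assert_array_equal(labels, labels2)
        np.testing.assert_array_equal(scores, scores2)

    def test_sign_symmetric_training_set_flips_labels(self):
        X = np.array([[-3.0], [-2.8], [-3.2], [3.0], [2.8], [3.2]])
        y = np.array([0, 0, 0, 1, 1, 1])
        model = RbfSvmClassifier(C=10.0, gamma=0.5).fit(X, y)
        probe = np.array([[-2.9], [2.9]])
        np.testing.assert_array_equal(model.predict(probe), [0, 1])
        np.testing.assert_array_equal(model.predict(-probe), [1, 0])

    def test_empty_feature_matrix_gives_empty_outputs(self, rng):
        fm = _clusters(20, 6.0, rng)
        model = fit_svm(fm, SVMConfig())
        labels, scores = predict(model, FeatureMatrix(np.empty((0, 2))))
        assert labels.size == 0 and scores.size == 0

    def test_schema_mismatch_rejected(self, rng):
        fm = _clusters(20, 6.0, rng)
        model = fit_svm(fm, SVMConfig())
        with pytest.raises(SchemaError):
            model.predict(np.ones((2, 5)))


class TestGridSearch:
    def test_results_table_is_exhaustive(self, rng):
        fm = _clusters(30, 6.0, rng)
        _, results = grid_search_cv(fm, GridSpec(k_folds=3))
        assert len(results) == 25
        assert set(results["C"]) == {0.1, 1.0, 10.0, 100.0, 1000.0}

    def test_separable_data_reaches_perfect_cv_accuracy(self, rng):
        fm = _clusters(30, 8.0, rng)
        best, results = grid_search_cv(fm, GridSpec(k_folds=3))
        assert results["mean_accuracy"].max() == 1.0

    def test_tie_broken_toward_smallest_c_then_gamma(self, rng):
        fm = _clusters(30, 12.0, rng)
        grid = GridSpec(C_values=(10.0, 1.0), gamma_values=(0.1, 0.01), k_folds=3)
        best, results = grid_search_cv(fm, grid)
        assert (results["mean_accuracy"] == 1.0).all()  # every combo ties
        assert (best.C, best.gamma) == (1.0, 0.01)

    def test_mean_accuracy_consistent_with_fold_columns(self, rng):
        fm = _clusters(25, 3.0, rng)
        _, results = grid_search_cv(fm, GridSpec(k_folds=5))
        fold_cols = [c for c in results.columns if c.startswith("fold")]
        np.testing.assert_allclose(
            results[fold_cols].mean(axis=1), results["mean_accuracy"], atol=1e-12
        )

    def test_folds_partition_training_data(self, rng):
        from sklearn.model_selection import StratifiedKFold
        fm = _clusters(25, 3.0, rng)
        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        seen = np.concatenate([val for _, val in cv.split(fm.X, fm.y)])
        assert sorted(seen) == list(range(fm.n_beats))

    def test_k_exceeding_minority_count_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([0] * 7 + [1] * 3)
        with pytest.raises(ValueError):
            grid_search_cv(FeatureMatrix(X, y), GridSpec(k_folds=5))

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(C_values=())
        with pytest.raises(ValueError):
            GridSpec(k_folds=1)
        with pytest.raises(ValueError):
            SVMConfig(C=-1.0)
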