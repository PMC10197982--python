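"""Label binarisation, splitting, CV tuning and score prediction."""

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from ecgkalemia.classifiers import (
    LabeledDataset,
    ModelSpec,
    binarize_labels,
    default_model_specs,
    predict_scores,
    split_dataset,
    tune_and_train,
)
from ecgkalemia.errors import SplitError, TrainingError, ValidationError
from ecgkalemia.evaluation import roc_auc
from ecgkalemia.features import FEATURE_VECTOR_NAMES


def _cohort_k():
    """Potassium values reproducing the emulated cohort's bin counts
    (576 / 173 / 136 / 85 / 54 across the 5.0/5.5/6.0/6.5 cuts)."""
    return np.concatenate([
        np.full(576, 4.2), np.full(173, 5.2), np.full(136, 5.7),
        np.full(85, 6.2), np.full(54, 6.8),
    ])


class TestBinarize:
    def test_prevalence_from_cohort_bins(self):
        k = _cohort_k()
        expected = {5.0: 448, 5.5: 275, 6.0: 139, 6.5: 54}
        for thr, n_pos in expected.items():
            y = binarize_labels(k, thr)
            assert int(y.sum()) == n_pos
        # printed to one decimal the positive fraction reads 43.8%
        assert round(100 * binarize_labels(k, 5.0).mean(), 1) == 43.8

    def test_equality_counts_as_positive(self):
        assert binarize_labels([5.0], 5.0).tolist() == [1]

    def test_all_below_gives_zeros(self):
        assert binarize_labels([3.0, 4.0], 5.0).tolist() == [0, 0]

    def test_noncanonical_threshold_warns(self):
        with pytest.warns(UserWarning):
            binarize_labels([5.0], 4.2)


class TestSplit:
    def test_1024_gives_205_test_rows(self):
        split = split_dataset(1024, 0.2, seed=0)
        assert split.test_indices.size == 205
        assert split.train_indices.size == 819

    def test_same_seed_identical(self):
        a = split_dataset(100, 0.2, seed=5)
        b = split_dataset(100, 0.2, seed=5)
        assert np.array_equal(a.test_indices, b.test_indices)

    def test_partition_is_disjoint_and_complete(self):
        split = split_dataset(97, 0.2, seed=1)
        both = np.concatenate([split.train_indices, split.test_indices])
        assert np.array_equal(np.sort(both), np.arange(97))

    def test_stratified_preserves_proportions_within_one(self):
        y = binarize_labels(_cohort_k(), 5.0)  # 448 positive / 576 negative
        split = split_dataset(1024, 0.2, seed=2, stratify_labels=y)
        n_test = split.test_indices.size
        test_pos = int(y[split.test_indices].sum())
        expect = 448 * n_test / 1024
        assert abs(test_pos - expect) <= 1
        train_pos = int(y[split.train_indices].sum())
        assert abs(train_pos - 448 * (1024 - n_test) / 1024) <= 1

    def test_tiny_dataset_rejected(self):
        with pytest.raises(SplitError):
            split_dataset(5, 0.2, seed=0)

    def test_singleton_class_rejected_under_stratification(self):
        y = np.zeros(20, dtype=int)
        y[3] = 1
        with pytest.raises(SplitError):
            split_dataset(20, 0.2, seed=0, stratify_labels=y)


def _synthetic_classification(n=200, seed=0, separable=False):
    """48-feature random data with signal in a handful of columns.

    With ``separable`` only two columns carry signal and the class margin
    has a clear gap, so every family should rank a held-out set perfectly.
    """
    rng = np.random.default_rng(seed)
    if separable:
        X = np.zeros((n, 48))
        margin = np.where(rng.random(n) < 0.5, 1.0, -1.0) * rng.uniform(0.5, 2.0, n)
        X[:, 3] = margin
        X[:, 15] = 0.5 * margin
        return X, (margin > 0).astype(int)
    X = rng.normal(size=(n, 48))
    w = np.zeros(48)
    w[[3, 15, 27, 39]] = 1.0
    margin = X @ w + rng.normal(0, 1.5, n)
    y = (margin > 0).astype(int)
    return X, y


class TestTuneAndTrain:
    def test_single_point_grid_selected_with_cv_report(self):
        X, y = _synthetic_classification()
        spec = ModelSpec("LR", {"C": [1.0]})
        model = tune_and_train(spec, X, y, seed=0)
        assert model.chosen_hyperparameters == {"C": 1.0}
        assert len(model.cv_results) == 1
        assert 0.5 < model.cv_results["mean_val_auc"].iloc[0] <= 1.0

    def test_selection_matches_independent_cv_loop(self):
        """The chosen grid point equals the argmax of an exhaustive CV loop
        coded here from scratch with the same folds."""
        from sklearn.linear_model import LogisticRegression

        X, y = _synthetic_classification(n=200, seed=1)
        grid = [0.01, 0.1, 1.0, 10.0]
        spec = ModelSpec("LR", {"C": grid})
        model = tune_and_train(spec, X, y, seed=7)

        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=7)
        folds = list(skf.split(X, y))
        means = []
        for c in grid:
            aucs = []
            for tr, va in folds:
                sc = StandardScaler().fit(X[tr])
                est = LogisticRegression(C=c, max_iter=5000, random_state=7)
                est.fit(sc.transform(X[tr]), y[tr])
                p = est.predict_proba(sc.transform(X[va]))[:, 1]
                aucs.append(roc_auc(y[va], p))
            means.append(np.mean(aucs))
        oracle_choice = grid[int(np.argmax(means))]
        assert model.chosen_hyperparameters["C"] == oracle_choice
        np.testing.assert_allclose(
            model.cv_results["mean_val_auc"].to_numpy(), means, atol=1e-9
        )

    @pytest.mark.parametrize("family", ["LR", "SVM", "XGB", "AdaBoost", "CNN"])
    def test_separable_data_reaches_auc_one(self, family):
        X, y = _synthetic_classification(n=120, seed=2, separable=True)
        Xte, yte = _synthetic_classification(n=80, seed=3, separable=True)
        spec = default_model_specs()[family]
        small = {k: v[:1] for k, v in spec.hyperparameter_grid.items()}
        model = tune_and_train(ModelSpec(family, small), X, y, seed=0)
        assert roc_auc(yte, predict_scores(model, Xte)) == 1.0

    def test_single_class_training_rejected(self):
        X, _ = _synthetic_classification(n=50)
        with pytest.raises(TrainingError):
            tune_and_train(ModelSpec("LR", {"C": [1.0]}), X,
                           np.zeros(50, dtype=int), seed=0)

    def test_scaler_fitted_on_training_data_only(self):
        X, y = _synthetic_classification(n=150, seed=4)
        model = tune_and_train(ModelSpec("LR", {"C": [1.0]}), X[:100], y[:100],
                               seed=0)
        np.testing.assert_allclose(model.scaler_mean, X[:100].mean(axis=0))
        # refitting on train+test must change the stored moments
        leaked = np.vstack([X[:100], X[100:]]).mean(axis=0)
        assert not np.allclose(model.scaler_mean, leaked)

    def test_determinism_given_seed(self):
        X, y = _synthetic_classification(n=150, seed=5)
        for family in ("LR", "XGB", "AdaBoost", "CNN"):
            spec = default_model_specs()[family]
            small = ModelSpec(family,
                              {k: v[:1] for k, v in
                               spec.hyperparameter_grid.items()})
            s1 = predict_scores(tune_and_train(small, X, y, seed=9), X)
            s2 = predict_scores(tune_and_train(small, X, y, seed=9), X)
            np.testing.assert_array_equal(s1, s2)


class TestPredictScores:
    def test_scores_in_unit_interval_and_right_length(self):
        X, y = _synthetic_classification(n=100, seed=6)
        for family in ("LR", "SVM"):
            spec = default_model_specs()[family]
            small = ModelSpec(family, {k: v[:1] for k, v in
                                       spec.hyperparameter_grid.items()})
            model = tune_and_train(small, X, y, seed=0)
            s = predict_scores(model, X)
            assert s.shape == (100,)
            assert np.all((s >= 0) & (s <= 1))

    def test_dataframe_column_order_irrelevant(self):
        X, y = _synthetic_classification(n=100, seed=7)
        model = tune_and_train(ModelSpec("LR", {"C": [1.0]}), X, y, seed=0)
        df = pd.DataFrame(X, columns=list(FEATURE_VECTOR_NAMES))
        shuffled = df[list(df.columns[::-1])]
        np.testing.assert_allclose(predict_scores(model, df),
                                   predict_scores(model, shuffled))

    def test_wrong_width_rejected(self):
        X, y = _synthetic_classification(n=60, seed=8)
        model = tune_and_train(ModelSpec("LR", {"C": [1.0]}), X, y, seed=0)
        with pytest.raises(ValidationError):
            predict_scores(model, X[:, :30])


class TestLabeledDataset:
    def test_frame_roundtrip(self):
        X, _ = _synthetic_classification(n=20, seed=9)
        ds = LabeledDataset(X, np.linspace(3, 7, 20),
                            [f"r{i}" for i in range(20)])
        back = LabeledDataset.from_frame(ds.to_frame())
        np.testing.assert_array_equal(back.features, ds.features)
        np.testing.assert_array_equal(back.k, ds.k)

    def test_mismatched_lengths_rejected(self):
        X, _ = _synthetic_classification(n=20, seed=9)
        with pytest.raises(ValidationError):
            LabeledDataset(X, np.ones(19), [f"r{i}" for i in range(20)])
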