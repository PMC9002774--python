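"""Classifier cells, the model-choice rule, and the nested CV designs."""

import warnings

import numpy as np
import pytest

from conftest import make_labeled_matrix
from fogdetect.modeling import (
    audit_no_leakage,
    choose_model,
    fit_predict,
    knn_cell,
    sda_fit_evaluate,
    sia_nested_loso,
    small_grid,
    svm_cell,
)


class TestFitPredict:
    def test_linear_svm_separable(self):
        rng = np.random.default_rng(0)
        X0 = rng.normal([-2, -2], 0.3, (50, 2))
        X1 = rng.normal([2, 2], 0.3, (50, 2))
        X = np.vstack([X0, X1])
        y = np.r_[np.zeros(50), np.ones(50)].astype(int)
        pred = fit_predict(svm_cell("linear"), X, y, X)
        assert (pred == y).all()

    def test_knn_k1_memorizes_training(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 3))
        y = (rng.random(40) < 0.5).astype(int)
        y[:2] = [0, 1]  # both classes present
        pred = fit_predict(knn_cell(1), X, y, X)
        np.testing.assert_array_equal(pred, y)

    def test_squared_euclidean_rank_equivalent(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((80, 4))
        y = (X[:, 0] > 0).astype(int)
        Xt = rng.standard_normal((30, 4))
        p1 = fit_predict(knn_cell(7, "euclidean", "equal"), X, y, Xt)
        p2 = fit_predict(knn_cell(7, "squared-euclidean", "equal"), X, y, Xt)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_training_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            fit_predict(svm_cell("linear"), X, np.zeros(10, dtype=int), X)


class TestChooseModel:
    def test_f_score_decides_on_split(self):
        scores = {"A": (0.85, 0.84), "B": (0.84, 0.85)}
        assert choose_model(scores) == "B"

    def test_dominating_model_wins(self):
        scores = {"A": (0.9, 0.9), "B": (0.84, 0.85)}
        assert choose_model(scores) == "A"

    def test_exact_tie_breaks_lexicographically(self):
        scores = {"B": (0.8, 0.8), "A": (0.8, 0.8)}
        assert choose_model(scores) == "A"


class TestNestedLOSO:
    def test_fold_structure(self):
        matrix = make_labeled_matrix(n_subjects=5, seed=3)
        cv = sia_nested_loso(matrix, grid=[svm_cell("linear"), knn_cell(5)])
        assert len(cv.folds) == 5
        assert all(f.n_inner_folds == 4 for f in cv.folds)
        assert sorted(f.test_id for f in cv.folds) == [
            "S01", "S02", "S03", "S04", "S05"
        ]

    def test_oracle_feature_gives_perfect_accuracy(self):
        matrix = make_labeled_matrix(n_subjects=4, seed=4)
        cv = sia_nested_loso(matrix, grid=[knn_cell(5)])
        assert (cv.predictions == matrix.labels).mean() > 0.99

    def test_leakage_audit_clean(self):
        matrix = make_labeled_matrix(n_subjects=4, seed=5)
        cv = sia_nested_loso(matrix, grid=[knn_cell(5)])
        for fold in cv.folds:
            audit_no_leakage(fold)
            assert set(fold.test_indices) & set(
                fold.fit_indices["final_fit"]
            ) == set()

    def test_label_permutation_yields_chance_level(self):
        """With labels shuffled within subjects, the nested LOSO accuracy
        stays at the majority-class rate (no leakage path)."""
        matrix = make_labeled_matrix(n_subjects=4, n_per_subject=150, seed=6)
        rng = np.random.default_rng(7)
        subjects = np.array([w.subject_id for w in matrix.windows.windows])
        for s in np.unique(subjects):
            idx = np.flatnonzero(subjects == s)
            labels = [matrix.windows.windows[i].label for i in idx]
            rng.shuffle(labels)
            for i, lab in zip(idx, labels):
                w = matrix.windows.windows[i]
                matrix.windows.windows[i] = type(w)(
                    w.subject_id, w.task_id, w.start_s, w.end_s, int(lab)
                )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv = sia_nested_loso(matrix, grid=[knn_cell(5)])
        y = matrix.labels
        majority_rate = max(y.mean(), 1 - y.mean())
        acc = (cv.predictions == y).mean()
        assert abs(acc - majority_rate) < 0.10

    def test_deterministic_given_seed(self):
        matrix = make_labeled_matrix(n_subjects=4, seed=8)
        cv1 = sia_nested_loso(matrix, grid=small_grid(), seed=1)
        cv2 = sia_nested_loso(matrix, grid=small_grid(), seed=1)
        np.testing.assert_array_equal(cv1.predictions, cv2.predictions)
        assert [f.model_id for f in cv1.folds] == [f.model_id for f in cv2.folds]

    def test_cohort_without_fog_degrades_to_majority(self):
        """A cohort where no window is FOG (e.g. no episodes survived the
        3-s exclusion) yields all-non-FOG majority predictions, not a crash."""
        matrix = make_labeled_matrix(n_subjects=3, seed=15, fog_fraction=0.0,
                                     oracle=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv = sia_nested_loso(matrix, grid=[knn_cell(5)])
        assert (cv.predictions == 0).all()
        assert all(f.model_id == "majority-class" for f in cv.folds)

    def test_too_few_subjects_rejected(self):
        matrix = make_labeled_matrix(n_subjects=2, seed=9)
        with pytest.raises(ValueError):
            sia_nested_loso(matrix, grid=[knn_cell(5)])


class TestSDA:
    def test_loto_fold_count(self):
        matrix = make_labeled_matrix(n_subjects=1, n_per_subject=240,
                                     n_tasks=4, seed=10)
        cv = sda_fit_evaluate(matrix, grid=[knn_cell(5)])
        assert len(cv.folds) == 4
        assert sorted(f.test_id for f in cv.folds) == ["T1", "T2", "T3", "T4"]

    def test_oracle_feature_near_perfect(self):
        matrix = make_labeled_matrix(n_subjects=1, n_per_subject=200,
                                     n_tasks=2, seed=11)
        cv = sda_fit_evaluate(matrix, grid=[knn_cell(5)])
        assert (cv.predictions == matrix.labels).mean() > 0.98

    def test_stratified_inner_folds_feasible(self):
        matrix = make_labeled_matrix(n_subjects=1, n_per_subject=200,
                                     n_tasks=4, seed=12)
        cv = sda_fit_evaluate(matrix, grid=[knn_cell(5)])
        # every fold trained on both classes and used stratified CV
        assert all(f.n_inner_folds >= 2 for f in cv.folds)

    def test_requires_fog_in_two_tasks(self):
        matrix = make_labeled_matrix(n_subjects=1, n_per_subject=120,
                                     n_tasks=2, seed=13)
        # wipe FOG labels from one task
        for i, w in enumerate(matrix.windows.windows):
            if w.task_id == "T2":
                matrix.windows.windows[i] = type(w)(
                    w.subject_id, w.task_id, w.start_s, w.end_s, 0
                )
        with pytest.raises(ValueError):
            sda_fit_evaluate(matrix, grid=[knn_cell(5)])

    def test_multi_subject_input_rejected(self):
        matrix = make_labeled_matrix(n_subjects=2, seed=14)
        with pytest.raises(ValueError):
            sda_fit_evaluate(matrix, grid=[knn_cell(5)])
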