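"""SVM / kNN training with nested, leakage-free cross-validation.

Two validation designs are provided:

* **Subject-independent (SIA)** — nested leave-one-subject-out: for each of N
  outer folds the held-out subject is the test set; an inner LOSO over the
  remaining N-1 subjects scores every (model family, hyperparameter) cell,
  the best cell (by mean inner F-score, with the accuracy/F-score model-choice
  rule) is refit on all N-1 subjects and applied to the held-out subject.
  Feature selection and range normalization are fitted inside the outer
  training set only.
* **Subject-dependent (SDA)** — per subject: 10-fold stratified CV on the
  training tasks' windows chooses the hyperparameters, and a leave-one-task-
  out loop provides the test predictions.

Hyperparameter ranges follow the study grid: SVM kernels linear / quadratic /
cubic / gaussian with kernel scale and cost in [0.1, 100]; kNN with 1-180
neighbours, cityblock / euclidean / squared-euclidean metrics and equal /
inverse / squared-inverse distance weights. Continuous ranges are sampled at
log-spaced points; the grid is configurable and a reduced preset is provided
for quick runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .features import FeatureMatrix, RangeNormalizer
from .selection import SelectionResult, select_features


@dataclass(frozen=True)
class ModelSpec:
    """One grid cell: a model family plus its hyperparameters."""

    family: str  # "svm" | "knn"
    params: tuple[tuple[str, object], ...]

    @property
    def param_dict(self) -> dict:
        return dict(self.params)

    @property
    def id(self) -> str:
        inner = ",".join(f"{k}={v}" for k, v in self.params)
        return f"{self.family}({inner})"


def svm_cell(kernel: str, kernel_scale: float = 1.0, cost: float = 1.0) -> ModelSpec:
    return ModelSpec(
        "svm",
        (("kernel", kernel), ("kernel_scale", float(kernel_scale)),
         ("cost", float(cost))),
    )


def knn_cell(n_neighbors: int, metric: str = "euclidean",
             weight: str = "equal") -> ModelSpec:
    return ModelSpec(
        "knn",
        (("n_neighbors", int(n_neighbors)), ("metric", metric),
         ("weight", weight)),
    )


def full_grid() -> list[ModelSpec]:
    """Desk-scale grid spanning the printed hyperparameter ranges."""
    scales = np.logspace(-1, 2, 5)
    cells = [
        svm_cell(kernel, s, c)
        for kernel in ("linear", "quadratic", "cubic", "gaussian")
        for s in scales
        for c in scales
    ]
    cells += [
        knn_cell(k, m, w)
        for k in (1, 5, 15, 45, 90, 180)
        for m in ("cityblock", "euclidean", "squared-euclidean")
        for w in ("equal", "inverse", "squared-inverse")
    ]
    return cells


def small_grid() -> list[ModelSpec]:
    """Reduced preset covering both families and kernel types, for runs where
    the full grid is unnecessary (strongly separated data, smoke tests)."""
    return [
        svm_cell("linear", 1.0, 1.0),
        svm_cell("linear", 1.0, 10.0),
        svm_cell("gaussian", 1.0, 10.0),
        knn_cell(5, "euclidean", "equal"),
        knn_cell(15, "euclidean", "inverse"),
    ]


def _inverse_sq(d: np.ndarray) -> np.ndarray:
    return 1.0 / np.maximum(d, 1e-12) ** 2


def build_estimator(spec: ModelSpec, seed: int = 0):
    p = spec.param_dict
    if spec.family == "svm":
        kernel = p["kernel"]
        scale = p["kernel_scale"]
        gamma = 1.0 / scale**2
        if kernel == "linear":
            return SVC(kernel="linear", C=p["cost"], random_state=seed)
        if kernel == "quadratic":
            return SVC(kernel="poly", degree=2, gamma=gamma, coef0=1.0,
                       C=p["cost"], random_state=seed)
        if kernel == "cubic":
            return SVC(kernel="poly", degree=3, gamma=gamma, coef0=1.0,
                       C=p["cost"], random_state=seed)
        if kernel == "gaussian":
            return SVC(kernel="rbf", gamma=gamma, C=p["cost"], random_state=seed)
        raise ValueError(f"unknown SVM kernel {kernel!r}")
    if spec.family == "knn":
        metric = {"cityblock": "manhattan", "euclidean": "euclidean",
                  "squared-euclidean": "sqeuclidean"}[p["metric"]]
        weights = {"equal": "uniform", "inverse": "distance",
                   "squared-inverse": _inverse_sq}[p["weight"]]
        return KNeighborsClassifier(
            n_neighbors=p["n_neighbors"], metric=metric, weights=weights,
            algorithm="brute",
        )
    raise ValueError(f"unknown model family {spec.family!r}")


def fit_predict(
    spec: ModelSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Train one grid cell and return hard 0/1 predictions on the test rows."""
    y_train = np.asarray(y_train, dtype=int)
    if np.unique(y_train).size < 2:
        raise ValueError("training set must contain both classes")
    est = build_estimator(spec, seed)
    if spec.family == "knn":
        k = spec.param_dict["n_neighbors"]
        if k > len(y_train):
            est.set_params(n_neighbors=len(y_train))
    est.fit(X_train, y_train)
    return est.predict(X_test).astype(int)


def _fold_scores(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """(accuracy, f_score) of one validation fold; F is 0 when undefined so a
    cell that never predicts the positive class cannot win the inner vote."""
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    acc = float(np.mean(pred == truth))
    tp = int(np.sum((pred == 1) & (truth == 1)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    f = 2.0 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    return acc, f


def choose_model(scores: dict[str, tuple[float, float]]) -> str:
    """Pick the model id given per-candidate (accuracy, f_score).

    The candidate with the maximum value of *both* metrics wins; if no single
    candidate dominates, the one with the maximum F-score is chosen.
    Exact ties break lexicographically by id.
    """
    if not scores:
        raise ValueError("no candidates")
    best_acc = max(a for a, _ in scores.values())
    best_f = max(f for _, f in scores.values())
    both = sorted(
        mid for mid, (a, f) in scores.items() if a == best_acc and f == best_f
    )
    if both:
        return both[0]
    return sorted(
        (mid for mid, (_, f) in scores.items() if f == best_f)
    )[0]


@dataclass
class FoldResult:
    """One outer test fold: what was chosen, what was predicted, what was fit on."""

    test_id: str
    model_id: str
    spec: ModelSpec | None
    test_indices: np.ndarray
    predictions: np.ndarray
    selected_features: list[str]
    inner_scores: dict[str, tuple[float, float]] = field(default_factory=dict)
    fit_indices: dict[str, np.ndarray] = field(default_factory=dict)
    selection: SelectionResult | None = None
    n_inner_folds: int = 0


def audit_no_leakage(fold: FoldResult) -> None:
    """Assert that no test row was used in any fitting step of its fold."""
    test = set(fold.test_indices.tolist())
    for step, idx in fold.fit_indices.items():
        overlap = test & set(np.asarray(idx).tolist())
        if overlap:
            raise AssertionError(
                f"leakage in fold {fold.test_id}: step {step} saw test rows "
                f"{sorted(overlap)[:5]}..."
            )


def _majority_predict(y_train: np.ndarray, n_test: int) -> np.ndarray:
    vals, counts = np.unique(np.asarray(y_train, dtype=int), return_counts=True)
    return np.full(n_test, int(vals[np.argmax(counts)]))


def _grid_eval_and_choose(
    X: pd.DataFrame,
    y: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    grid: list[ModelSpec],
    seed: int,
) -> tuple[str, ModelSpec, dict[str, tuple[float, float]]]:
    """Score every grid cell over the given (train, val) index folds and apply
    the model-choice rule to the per-cell mean scores."""
    cell_scores: dict[str, list[tuple[float, float]]] = {c.id: [] for c in grid}
    specs = {c.id: c for c in grid}
    for tr, va in folds:
        for cell in grid:
            pred = fit_predict(
                cell, X.iloc[tr].to_numpy(), y[tr], X.iloc[va].to_numpy(), seed
            )
            cell_scores[cell.id].append(_fold_scores(pred, y[va]))
    mean_scores = {
        cid: (
            float(np.mean([a for a, _ in sc])),
            float(np.mean([f for _, f in sc])),
        )
        for cid, sc in cell_scores.items()
        if sc
    }
    chosen = choose_model(mean_scores)
    return chosen, specs[chosen], mean_scores


@dataclass
class CrossValidationResult:
    """All folds of one SIA or SDA run, with row-aligned pooled predictions."""

    folds: list[FoldResult]
    predictions: np.ndarray  # aligned with the input feature-matrix rows
    evaluated: np.ndarray  # boolean mask of rows that belong to some test fold
    mode: str


def sia_nested_loso(
    matrix: FeatureMatrix,
    grid: list[ModelSpec] | None = None,
    r_thresh: float | None = None,
    seed: int = 0,
    selection_scope: str = "fold",
) -> CrossValidationResult:
    """Nested leave-one-subject-out evaluation of the subject-independent
    algorithm.

    ``selection_scope='fold'`` (default) fits feature selection inside each
    outer training set; ``'all'`` reproduces the variant where selection is
    run once on the pooled data of every subject before cross-validation.
    """
    if grid is None:
        grid = full_grid()
    windows = matrix.windows.windows
    subjects = np.array([w.subject_id for w in windows])
    y = matrix.labels
    unique_subjects = sorted(set(subjects))
    with_both = [
        s for s in unique_subjects if np.unique(y[subjects == s]).size == 2
    ]
    if len(unique_subjects) < 3:
        raise ValueError("nested LOSO requires at least 3 subjects")

    global_selection: SelectionResult | None = None
    if selection_scope == "all":
        norm_all = RangeNormalizer()
        global_selection = select_features(
            norm_all.fit_transform(matrix.data), y, mode="SIA", r_thresh=r_thresh
        )

    predictions = np.full(len(y), -1, dtype=int)
    folds: list[FoldResult] = []
    for test_subject in unique_subjects:
        test_idx = np.flatnonzero(subjects == test_subject)
        train_idx = np.flatnonzero(subjects != test_subject)
        norm = RangeNormalizer()
        X_train_all = norm.fit_transform(matrix.data.iloc[train_idx])
        if selection_scope == "all":
            sel = global_selection
        elif np.unique(y[train_idx]).size < 2:
            # single-class training cohort (e.g. no FOG observed): nothing to
            # select against; fall through to the majority-class fold below
            sel = SelectionResult([], pd.Series(dtype=float),
                                  pd.Series(dtype=float), mode="SIA")
        else:
            sel = select_features(
                X_train_all, y[train_idx], mode="SIA", r_thresh=r_thresh
            )
        fit_steps = {
            "normalization": train_idx,
            "selection": train_idx,
            "grid_search": train_idx,
            "final_fit": train_idx,
        }
        if not sel.retained:
            warnings.warn(
                f"no feature passed selection for test subject {test_subject}; "
                "predicting the training majority class",
                stacklevel=2,
            )
            pred = _majority_predict(y[train_idx], test_idx.size)
            fold = FoldResult(
                test_subject, "majority-class", None, test_idx, pred, [],
                {}, fit_steps, sel,
            )
            predictions[test_idx] = pred
            folds.append(fold)
            continue

        X_train = X_train_all[sel.retained]
        y_train = y[train_idx]
        inner_subjects = subjects[train_idx]
        inner_folds = []
        for val_subject in sorted(set(inner_subjects)):
            if val_subject not in with_both:
                warnings.warn(
                    f"subject {val_subject} lacks both classes; excluded from "
                    "inner validation",
                    stacklevel=2,
                )
                continue
            va = np.flatnonzero(inner_subjects == val_subject)
            tr = np.flatnonzero(inner_subjects != val_subject)
            if np.unique(y_train[tr]).size < 2:
                continue
            inner_folds.append((tr, va))
        if not inner_folds:
            raise ValueError(
                f"no usable inner validation folds for test subject {test_subject}"
            )
        chosen_id, chosen_spec, mean_scores = _grid_eval_and_choose(
            X_train, y_train, inner_folds, grid, seed
        )
        X_test = norm.transform(matrix.data.iloc[test_idx])[sel.retained]
        pred = fit_predict(
            chosen_spec, X_train.to_numpy(), y_train, X_test.to_numpy(), seed
        )
        predictions[test_idx] = pred
        folds.append(
            FoldResult(
                test_subject, chosen_id, chosen_spec, test_idx, pred,
                list(sel.retained), mean_scores, fit_steps, sel,
                n_inner_folds=len(inner_folds),
            )
        )
    return CrossValidationResult(
        folds, predictions, predictions >= 0, mode="SIA"
    )


def sda_fit_evaluate(
    matrix: FeatureMatrix,
    grid: list[ModelSpec] | None = None,
    r_thresh: float | None = None,
    n_cv_folds: int = 10,
    seed: int = 0,
) -> CrossValidationResult:
    """Subject-dependent evaluation for the (single) subject in ``matrix``:
    10-fold stratified CV for hyperparameter choice, leave-one-task-out for
    the test predictions. Requires FOG windows in at least 2 tasks."""
    if grid is None:
        grid = full_grid()
    if r_thresh is None:
        r_thresh = 0.4
    windows = matrix.windows.windows
    subjects = {w.subject_id for w in windows}
    if len(subjects) != 1:
        raise ValueError("SDA operates on a single subject's windows")
    tasks = np.array([w.task_id for w in windows])
    y = matrix.labels
    tasks_with_fog = [t for t in sorted(set(tasks)) if y[tasks == t].sum() > 0]
    if len(tasks_with_fog) < 2:
        raise ValueError(
            "subject has FOG windows in fewer than 2 tasks; LOTO is not possible"
        )
    predictions = np.full(len(y), -1, dtype=int)
    folds: list[FoldResult] = []
    for test_task in sorted(set(tasks)):
        test_idx = np.flatnonzero(tasks == test_task)
        train_idx = np.flatnonzero(tasks != test_task)
        y_train = y[train_idx]
        if np.unique(y_train).size < 2:
            warnings.warn(
                f"training tasks for held-out {test_task} lack both classes; "
                "skipping fold",
                stacklevel=2,
            )
            continue
        norm = RangeNormalizer()
        X_train_all = norm.fit_transform(matrix.data.iloc[train_idx])
        sel = select_features(X_train_all, y_train, mode="SDA", r_thresh=r_thresh)
        fit_steps = {
            "normalization": train_idx,
            "selection": train_idx,
            "grid_search": train_idx,
            "final_fit": train_idx,
        }
        if not sel.retained:
            pred = _majority_predict(y_train, test_idx.size)
            predictions[test_idx] = pred
            folds.append(
                FoldResult(test_task, "majority-class", None, test_idx, pred,
                           [], {}, fit_steps, sel)
            )
            continue
        X_train = X_train_all[sel.retained]
        n_minority = int(min(np.bincount(y_train)))
        n_splits = max(2, min(n_cv_folds, n_minority))
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        cv_folds = [
            (tr, va) for tr, va in skf.split(X_train, y_train)
            if np.unique(y_train[tr]).size == 2
        ]
        chosen_id, chosen_spec, mean_scores = _grid_eval_and_choose(
            X_train, y_train, cv_folds, grid, seed
        )
        X_test = norm.transform(matrix.data.iloc[test_idx])[sel.retained]
        pred = fit_predict(
            chosen_spec, X_train.to_numpy(), y_train, X_test.to_numpy(), seed
        )
        predictions[test_idx] = pred
        folds.append(
            FoldResult(test_task, chosen_id, chosen_spec, test_idx, pred,
                       list(sel.retained), mean_scores, fit_steps, sel,
                       n_inner_folds=len(cv_folds))
        )
    return CrossValidationResult(folds, predictions, predictions >= 0, mode="SDA")


__all__ = [
    "ModelSpec",
    "svm_cell",
    "knn_cell",
    "full_grid",
    "small_grid",
    "build_estimator",
    "fit_predict",
    "choose_model",
    "FoldResult",
    "CrossValidationResult",
    "audit_no_leakage",
    "sia_nested_loso",
    "sda_fit_evaluate",
]
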