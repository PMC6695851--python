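"""Subject-level stratified 10-fold cross-validation.

Normalization and hyperparameter selection are re-fit inside each
training fold only (nested inner CV for grids), so the test fold never
leaks into model selection.  The pooled confusion matrix sums the ten
test-fold matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import DataError
from ._gridsearch import stratified_folds
from .features import LabeledSubject, feature_matrix
from .knn import KNNClassifier, knn_grid_search
from .metrics import ConfusionMatrix, confusion_from_predictions
from .nbc import GaussianNBC
from .normalize import apply_normalizer, fit_normalizer
from .svm import DEFAULT_C_GRID, DEFAULT_SIGMA_GRID, RBFSVM, svm_grid_search

__all__ = ["ClassifierSpec", "CVResult", "crossvalidate", "make_folds"]

DEFAULT_K_GRID: tuple[int, ...] = (1, 3, 5, 7, 9, 11, 13, 15)


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to run and with what hyperparameter grids."""

    name: str  # 'knn' | 'nbc' | 'svm'
    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    sigma_grid: tuple[float, ...] = DEFAULT_SIGMA_GRID

    def __post_init__(self) -> None:
        if self.name not in ("knn", "nbc", "svm"):
            raise DataError(f"unknown classifier {self.name!r}")


@dataclass
class CVResult:
    per_fold: list[ConfusionMatrix]
    pooled: ConfusionMatrix
    fold_indices: list[np.ndarray]
    selected_params: list[dict] = field(default_factory=list)
    seed: int = 0


def make_folds(
    y: np.ndarray, n_folds: int, seed: int
) -> list[np.ndarray]:
    """Stratified, disjoint, exhaustive folds (sizes differ by <= 1)."""
    return stratified_folds(np.asarray(y), n_folds, np.random.default_rng(seed))


def _fit_predict(
    spec: ClassifierSpec,
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_te: np.ndarray,
    seed: int,
) -> tuple[np.ndarray, dict]:
    if spec.name == "knn":
        k = knn_grid_search(X_tr, y_tr, list(spec.k_grid), seed=seed)
        model = KNNClassifier(k).fit(X_tr, y_tr)
        return model.predict(X_te), {"k": k}
    if spec.name == "nbc":
        model = GaussianNBC().fit(X_tr, y_tr)
        return model.predict(X_te), {}
    C, sigma = svm_grid_search(
        X_tr, y_tr, spec.C_grid, spec.sigma_grid, seed=seed
    )
    model = RBFSVM(C=C, sigma=sigma).fit(X_tr, y_tr)
    return model.predict(X_te), {"C": C, "sigma": sigma}


def crossvalidate(
    subjects: list[LabeledSubject],
    task: str,
    spec: ClassifierSpec,
    seed: int,
    n_folds: int = 10,
) -> CVResult:
    """Run the full subject-level CV protocol for one classifier.

    Deterministic under ``seed``: fold assignment and every inner grid
    search derive their randomness from it.
    """
    X, y = feature_matrix(subjects, task)
    if X.shape[0] < n_folds:
        raise DataError(
            f"{X.shape[0]} subjects cannot be split into {n_folds} folds"
        )
    folds = make_folds(y, n_folds, seed)
    per_fold: list[ConfusionMatrix] = []
    selected: list[dict] = []
    pooled = ConfusionMatrix(0, 0, 0, 0)
    for i, test_idx in enumerate(folds):
        train_mask = np.ones(y.size, dtype=bool)
        train_mask[test_idx] = False
        X_tr, y_tr = X[train_mask], y[train_mask]
        norm = fit_normalizer(X_tr)
        Z_tr = apply_normalizer(norm, X_tr)
        Z_te = apply_normalizer(norm, X[test_idx])
        y_pred, params = _fit_predict(spec, Z_tr, y_tr, Z_te, seed=seed + i)
        cm = confusion_from_predictions(y[test_idx], y_pred)
        per_fold.append(cm)
        selected.append(params)
        pooled = pooled + cm
    if pooled.total != len(subjects):
        raise DataError("fold bookkeeping error: pooled total != cohort size")
    return CVResult(
        per_fold=per_fold,
        pooled=pooled,
        fold_indices=folds,
        selected_params=selected,
        seed=seed,
    )
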