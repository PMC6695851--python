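"""k-nearest-neighbour classifier with deterministic tie handling.

Euclidean distances; majority vote among the k nearest.  Vote ties break
to the class with the smaller summed neighbour distance, then to the
positive class.  Distance ties break by training-set order (stable sort).
"""

from __future__ import annotations

import numpy as np

from ..errors import DataError
from ._gridsearch import inner_cv_accuracy

__all__ = ["KNNClassifier", "knn_classify", "knn_grid_search"]


class KNNClassifier:
    """Minimal fit/predict wrapper around :func:`knn_classify`."""

    def __init__(self, k: int):
        if k < 1:
            raise DataError("k must be >= 1")
        self.k = k
        self._X: np.ndarray | None = None
        self._y: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KNNClassifier":
        X, y = np.asarray(X, float), np.asarray(y, int)
        if X.shape[0] == 0:
            raise DataError("empty training set")
        if self.k > X.shape[0]:
            raise DataError(f"k={self.k} exceeds training size {X.shape[0]}")
        self._X, self._y = X, y
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._X is None:
            raise DataError("classifier not fitted")
        X = np.atleast_2d(np.asarray(X, float))
        return np.array(
            [knn_classify(self._X, self._y, x, self.k) for x in X], dtype=int
        )


def knn_classify(
    train_X: np.ndarray, train_y: np.ndarray, x: np.ndarray, k: int
) -> int:
    """Label of ``x`` by majority vote among its k nearest training points."""
    train_X = np.asarray(train_X, float)
    train_y = np.asarray(train_y, int)
    if train_X.shape[0] == 0:
        raise DataError("empty training set")
    if not 1 <= k <= train_X.shape[0]:
        raise DataError(f"k={k} outside [1, {train_X.shape[0]}]")
    dist = np.linalg.norm(train_X - np.asarray(x, float), axis=1)
    order = np.argsort(dist, kind="stable")[:k]
    labels = train_y[order]
    d = dist[order]
    votes_pos = int(np.count_nonzero(labels == 1))
    votes_neg = k - votes_pos
    if votes_pos != votes_neg:
        return 1 if votes_pos > votes_neg else -1
    sum_pos = float(d[labels == 1].sum())
    sum_neg = float(d[labels == -1].sum())
    if sum_pos != sum_neg:
        return 1 if sum_pos < sum_neg else -1
    return 1


def knn_grid_search(
    X: np.ndarray,
    y: np.ndarray,
    k_grid: list[int],
    seed: int,
    n_inner_folds: int = 5,
) -> int:
    """k maximizing inner stratified-CV accuracy; ties -> smallest k.

    Only odd k are accepted, so plain vote ties cannot arise.
    """
    if not k_grid:
        raise DataError("empty k grid")
    if any(k % 2 == 0 for k in k_grid):
        raise DataError("k grid must contain odd values only")
    best_k, best_acc = None, -1.0
    for k in sorted(k_grid):
        try:
            acc = inner_cv_accuracy(
                lambda: KNNClassifier(k), X, y, seed=seed, n_folds=n_inner_folds
            )
        except DataError:
            continue  # k too large for the inner training folds
        if acc > best_acc:
            best_k, best_acc = k, acc
    if best_k is None:
        raise DataError("no feasible k in grid for this training-set size")
    return best_k
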