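"""Shared inner-CV machinery for hyperparameter grid searches.

Model selection never sees the outer test fold: candidates are scored by
stratified k-fold accuracy inside the training fold only.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from ..errors import DataError

__all__ = ["stratified_folds", "inner_cv_accuracy"]


def stratified_folds(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Deterministic stratified partition into ``n_folds`` index arrays.

    Class members are shuffled then dealt round-robin across folds with a
    running fold pointer, so overall fold sizes differ by at most one.
    """
    y = np.asarray(y)
    n = y.size
    if n_folds < 2 or n_folds > n:
        raise DataError(f"cannot make {n_folds} folds from {n} subjects")
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    pointer = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(idx.size)]
        for i in idx:
            folds[pointer % n_folds].append(int(i))
            pointer += 1
    return [np.array(sorted(f), dtype=int) for f in folds]


def inner_cv_accuracy(
    make_model: Callable,
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    n_folds: int = 5,
) -> float:
    """Pooled accuracy of ``make_model()`` over an inner stratified CV."""
    rng = np.random.default_rng(seed)
    n_folds = min(n_folds, int(np.min(np.bincount((y == 1).astype(int)))), y.size)
    n_folds = max(n_folds, 2)
    folds = stratified_folds(y, n_folds, rng)
    correct = 0
    for test_idx in folds:
        train_mask = np.ones(y.size, dtype=bool)
        train_mask[test_idx] = False
        if np.unique(y[train_mask]).size < 2:
            continue
        model = make_model().fit(X[train_mask], y[train_mask])
        correct += int(np.count_nonzero(model.predict(X[test_idx]) == y[test_idx]))
    return correct / y.size
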