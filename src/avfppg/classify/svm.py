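"""Soft-margin SVM with the radial-basis kernel exp(-||xi - xj||^2 / sigma).

The box-constrained dual is solved by libsvm (via scikit-learn) at a
tight tolerance; the full dual solution (alpha for every training point,
bias b) plus the dual objective and KKT residuals are exposed so the
optimality conditions can be verified independently of the solver.

Note the kernel scale convention: ``sigma`` divides the *squared*
distance, i.e. gamma = 1/sigma in the usual RBF parameterization.
"""

from __future__ import annotations

import numpy as np
from sklearn.svm import SVC

from ..errors import DataError, TrainingError
from ._gridsearch import inner_cv_accuracy

__all__ = ["RBFSVM", "svm_fit", "svm_grid_search", "rbf_kernel"]

DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_SIGMA_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-5, 11, 2))


def rbf_kernel(A: np.ndarray, B: np.ndarray, sigma: float) -> np.ndarray:
    """Gram matrix exp(-||a - b||^2 / sigma)."""
    A, B = np.atleast_2d(A), np.atleast_2d(B)
    sq = (
        np.sum(A**2, axis=1)[:, None]
        + np.sum(B**2, axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    return np.exp(-np.maximum(sq, 0.0) / sigma)


class RBFSVM:
    """Binary soft-margin SVM; labels must be +1/-1."""

    def __init__(self, C: float, sigma: float, tol: float = 1e-10):
        if C <= 0 or sigma <= 0:
            raise DataError("C and sigma must be positive")
        self.C = C
        self.sigma = sigma
        self.tol = tol
        self.alpha_: np.ndarray | None = None
        self.b_: float = 0.0
        self._X: np.ndarray | None = None
        self._y: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RBFSVM":
        X, y = np.asarray(X, float), np.asarray(y, int)
        if set(np.unique(y)) != {-1, 1}:
            raise DataError("both labels +1 and -1 must be present")
        svc = SVC(
            C=self.C,
            kernel="rbf",
            gamma=1.0 / self.sigma,
            tol=self.tol,
            shrinking=False,
            max_iter=10_000_000,
        )
        svc.fit(X, y)
        if svc.fit_status_ != 0 or np.any(svc.n_iter_ >= 10_000_000):
            raise TrainingError(
                f"SVM dual solver did not converge (C={self.C}, sigma={self.sigma})"
            )
        alpha = np.zeros(X.shape[0])
        alpha[svc.support_] = np.abs(svc.dual_coef_[0])
        self.alpha_ = alpha
        self.b_ = float(svc.intercept_[0])
        self._X, self._y = X, y
        return self

    # -- decision and diagnostics ------------------------------------------

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted()
        K = rbf_kernel(self._X, X, self.sigma)
        return (self.alpha_ * self._y) @ K + self.b_

    def predict(self, X: np.ndarray) -> np.ndarray:
        f = self.decision_function(np.atleast_2d(np.asarray(X, float)))
        return np.where(f >= 0, 1, -1)

    def dual_objective(self) -> float:
        """sum(alpha) - 1/2 alpha' diag(y) K diag(y) alpha at the solution."""
        self._check_fitted()
        K = rbf_kernel(self._X, self._X, self.sigma)
        ay = self.alpha_ * self._y
        return float(np.sum(self.alpha_) - 0.5 * ay @ K @ ay)

    def kkt_residuals(self) -> dict[str, float]:
        """Optimality diagnostics at the returned dual solution.

        ``equality``: |sum(alpha_j y_j)|; ``bounds``: worst violation of
        0 <= alpha <= C; ``complementarity``: worst violation of the
        margin conditions (alpha=0 -> margin >= 1; 0<alpha<C ->
        margin = 1; alpha=C -> margin <= 1).
        """
        self._check_fitted()
        m = self._y * self.decision_function(self._X)
        a = self.alpha_
        eps = 1e-8 * max(self.C, 1.0)
        at_zero = a <= eps
        at_c = a >= self.C - eps
        interior = ~at_zero & ~at_c
        res = 0.0
        if np.any(at_zero):
            res = max(res, float(np.max(np.maximum(0.0, 1.0 - m[at_zero]))))
        if np.any(interior):
            res = max(res, float(np.max(np.abs(1.0 - m[interior]))))
        if np.any(at_c):
            res = max(res, float(np.max(np.maximum(0.0, m[at_c] - 1.0))))
        return {
            "equality": float(abs(np.sum(a * self._y))),
            "bounds": float(
                max(np.max(np.maximum(0.0, -a)), np.max(np.maximum(0.0, a - self.C)))
            ),
            "complementarity": res,
        }

    def _check_fitted(self) -> None:
        if self.alpha_ is None:
            raise DataError("SVM not fitted")


def svm_fit(X: np.ndarray, y: np.ndarray, C: float, sigma: float) -> RBFSVM:
    return RBFSVM(C=C, sigma=sigma).fit(X, y)


def svm_grid_search(
    X: np.ndarray,
    y: np.ndarray,
    C_grid: tuple[float, ...] = DEFAULT_C_GRID,
    sigma_grid: tuple[float, ...] = DEFAULT_SIGMA_GRID,
    seed: int = 0,
    n_inner_folds: int = 5,
) -> tuple[float, float]:
    """(C, sigma) maximizing inner stratified-CV accuracy.

    Ties prefer the smaller C, then the larger sigma (the smoother,
    less-penalized model).
    """
    if not C_grid or not sigma_grid:
        raise DataError("hyperparameter grids must be nonempty")
    best, best_acc = None, -1.0
    for C in sorted(C_grid):
        for sigma in sorted(sigma_grid, reverse=True):
            acc = inner_cv_accuracy(
                lambda: RBFSVM(C=C, sigma=sigma, tol=1e-3),
                X,
                y,
                seed=seed,
                n_folds=n_inner_folds,
            )
            if acc > best_acc:
                best, best_acc = (C, sigma), acc
    assert best is not None
    return best
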