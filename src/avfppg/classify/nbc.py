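"""Gaussian naive Bayes classifier.

Per-class, per-feature Gaussian likelihoods under the independence
assumption, priors from class frequencies, maximum-a-posteriori label.
A variance floor of 1e-9 guards degenerate features; exact posterior
ties resolve to the positive class.
"""

from __future__ import annotations

import numpy as np

from ..errors import DataError

__all__ = ["GaussianNBC", "nbc_fit", "nbc_classify"]

VARIANCE_FLOOR = 1e-9


class GaussianNBC:
    classes_ = (1, -1)

    def __init__(self) -> None:
        self.means_: dict[int, np.ndarray] = {}
        self.vars_: dict[int, np.ndarray] = {}
        self.priors_: dict[int, float] = {}

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GaussianNBC":
        X, y = np.asarray(X, float), np.asarray(y, int)
        for cls in self.classes_:
            rows = X[y == cls]
            if rows.shape[0] < 2:
                raise DataError(
                    f"class {cls:+d} has {rows.shape[0]} training points; need >= 2"
                )
            self.means_[cls] = rows.mean(axis=0)
            self.vars_[cls] = np.maximum(rows.var(axis=0), VARIANCE_FLOOR)
            self.priors_[cls] = rows.shape[0] / X.shape[0]
        return self

    def log_joint(self, x: np.ndarray) -> dict[int, float]:
        """log(prior * product of feature likelihoods) per class."""
        out = {}
        for cls in self.classes_:
            mu, var = self.means_[cls], self.vars_[cls]
            ll = -0.5 * np.sum(np.log(2.0 * np.pi * var) + (x - mu) ** 2 / var)
            out[cls] = float(np.log(self.priors_[cls]) + ll)
        return out

    def posteriors(self, x: np.ndarray) -> dict[int, float]:
        lj = self.log_joint(np.asarray(x, float))
        m = max(lj.values())
        w = {c: np.exp(v - m) for c, v in lj.items()}
        z = sum(w.values())
        return {c: v / z for c, v in w.items()}

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        out = []
        for x in X:
            lj = self.log_joint(x)
            # tie -> positive
            out.append(1 if lj[1] >= lj[-1] else -1)
        return np.array(out, dtype=int)


def nbc_fit(X: np.ndarray, y: np.ndarray) -> GaussianNBC:
    return GaussianNBC().fit(X, y)


def nbc_classify(model: GaussianNBC, x: np.ndarray) -> int:
    return int(model.predict(np.atleast_2d(x))[0])
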