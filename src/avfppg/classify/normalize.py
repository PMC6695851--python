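"""Per-feature affine normalization to [-1, 1] on the training range."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import DataError

__all__ = ["NormalizationParams", "fit_normalizer", "apply_normalizer"]


@dataclass(frozen=True)
class NormalizationParams:
    lo: np.ndarray  # training minimum per feature  -> maps to -1
    hi: np.ndarray  # training maximum per feature  -> maps to +1


def fit_normalizer(X: np.ndarray) -> NormalizationParams:
    """Fit min/max per feature on training rows.

    Constant features are degenerate (the map is undefined) and rejected.
    """
    X = np.asarray(X, dtype=float)
    lo, hi = X.min(axis=0), X.max(axis=0)
    if np.any(hi <= lo):
        bad = np.flatnonzero(hi <= lo).tolist()
        raise DataError(f"constant feature column(s) {bad}; cannot normalize")
    return NormalizationParams(lo=lo, hi=hi)


def apply_normalizer(params: NormalizationParams, X: np.ndarray) -> np.ndarray:
    """Affine map of each feature: training min -> -1, max -> +1.

    Values outside the training range extrapolate (no clipping).
    """
    X = np.asarray(X, dtype=float)
    return 2.0 * (X - params.lo) / (params.hi - params.lo) - 1.0
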