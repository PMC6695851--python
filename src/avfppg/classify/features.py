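"""Feature vectors and labeled subjects for the two screening tasks.

The stenosis (DOS) task uses five features; the flow (BFV) task adds
heart rate.  Label polarity follows the clinical convention used
throughout: *positive* means the fistula passes the check (DOS < 30%,
BFV > 600 mL/min), so a false negative flags a healthy access — the
costly error is the false *positive* direction for disease.  Type II
error below is always the false-negative rate under this polarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import DataError, DomainError

DOS_FEATURES: tuple[str, ...] = ("pi_max", "pi_min", "spo2", "sbp", "dbp")
BFV_FEATURES: tuple[str, ...] = DOS_FEATURES + ("hr",)

#: Clinical decision thresholds.
DOS_THRESHOLD_PCT = 30.0
BFV_THRESHOLD_ML_MIN = 600.0


def task_features(task: str) -> tuple[str, ...]:
    if task == "dos":
        return DOS_FEATURES
    if task == "bfv":
        return BFV_FEATURES
    raise DataError(f"unknown task {task!r}; expected 'dos' or 'bfv'")


@dataclass(frozen=True)
class FeatureVector:
    """The six measurable inputs; ``hr`` participates only in the BFV task."""

    pi_max: float
    pi_min: float
    spo2: float
    sbp: float
    dbp: float
    hr: float

    def __post_init__(self) -> None:
        if not self.pi_max >= self.pi_min > 0:
            raise DomainError(
                f"need pi_max >= pi_min > 0, got {self.pi_max}, {self.pi_min}"
            )
        if self.sbp <= self.dbp:
            raise DomainError(f"need sbp > dbp, got {self.sbp} <= {self.dbp}")

    def to_array(self, task: str) -> np.ndarray:
        return np.array([getattr(self, f) for f in task_features(task)])


@dataclass(frozen=True)
class LabeledSubject:
    """One subject: features, binary labels (+1/-1) and optional ground truth."""

    subject_id: str
    features: FeatureVector
    dos_label: int = 0
    bfv_label: int = 0
    dos_pct: float | None = None
    bfv_ml_min: float | None = None

    def label(self, task: str) -> int:
        return self.dos_label if task == "dos" else self.bfv_label


def feature_matrix(
    subjects: list[LabeledSubject], task: str
) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) arrays for a task; y in {+1, -1}."""
    names = task_features(task)
    X = np.array(
        [[getattr(s.features, f) for f in names] for s in subjects], dtype=float
    )
    y = np.array([s.label(task) for s in subjects], dtype=int)
    if np.any(~np.isin(y, (-1, 1))):
        raise DataError("labels must be +1 or -1 for classification")
    return X, y


def subjects_to_frame(subjects: list[LabeledSubject]) -> pd.DataFrame:
    """Feature-table dialect used on disk (one row per subject)."""
    rows = []
    for s in subjects:
        rows.append(
            {
                "subject_id": s.subject_id,
                "pi_max": s.features.pi_max,
                "pi_min": s.features.pi_min,
                "spo2": s.features.spo2,
                "sbp": s.features.sbp,
                "dbp": s.features.dbp,
                "hr": s.features.hr,
                "dos_pct": s.dos_pct,
                "bfv_ml_min": s.bfv_ml_min,
                "dos_label": s.dos_label,
                "bfv_label": s.bfv_label,
            }
        )
    return pd.DataFrame(rows)


def subjects_from_frame(df: pd.DataFrame) -> list[LabeledSubject]:
    required = {"subject_id", "pi_max", "pi_min", "spo2", "sbp", "dbp", "hr"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"feature table missing columns: {sorted(missing)}")
    subjects = []
    for _, row in df.iterrows():
        fv = FeatureVector(
            pi_max=float(row["pi_max"]),
            pi_min=float(row["pi_min"]),
            spo2=float(row["spo2"]),
            sbp=float(row["sbp"]),
            dbp=float(row["dbp"]),
            hr=float(row["hr"]),
        )
        subjects.append(
            LabeledSubject(
                subject_id=str(row["subject_id"]),
                features=fv,
                dos_label=int(row.get("dos_label", 0) or 0),
                bfv_label=int(row.get("bfv_label", 0) or 0),
                dos_pct=_opt_float(row, "dos_pct"),
                bfv_ml_min=_opt_float(row, "bfv_ml_min"),
            )
        )
    return subjects


def _opt_float(row: pd.Series, key: str) -> float | None:
    if key not in row or pd.isna(row[key]):
        return None
    return float(row[key])
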