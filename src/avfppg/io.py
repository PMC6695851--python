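"""Delimited-text I/O for waveforms and feature tables.

Waveforms live in CSV with either a ``time,amplitude`` pair of columns
or a single amplitude column plus a ``# fs=<Hz>`` header line.  Comment
lines start with ``#``.  Feature tables use the cohort CSV dialect of
:mod:`avfppg.classify.features`.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .classify.features import LabeledSubject, subjects_from_frame, subjects_to_frame
from .errors import DataError
from .readout_dsp import PPGWaveform

__all__ = [
    "read_waveform",
    "write_waveform",
    "read_feature_table",
    "write_feature_table",
]


def write_waveform(path: str | Path, w: PPGWaveform) -> None:
    """Single-column dialect with the sampling rate in a header comment."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={w.fs:g}\n")
        fh.write("amplitude\n")
        np.savetxt(fh, w.samples, fmt="%.10g")


def read_waveform(path: str | Path) -> PPGWaveform:
    path = Path(path)
    fs = None
    body_lines: list[str] = []
    with path.open() as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                meta = stripped.lstrip("#").strip()
                if meta.startswith("fs="):
                    try:
                        fs = float(meta[3:])
                    except ValueError as exc:
                        raise DataError(f"bad fs header in {path}: {meta}") from exc
                continue
            body_lines.append(line)
    if not body_lines:
        raise DataError(f"no samples in {path}")
    df = pd.read_csv(_io.StringIO("".join(body_lines)))
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "time" in cols and "amplitude" in cols:
        t = df["time"].to_numpy(dtype=float)
        dt = np.diff(t)
        if t.size < 2 or np.any(dt <= 0):
            raise DataError(f"non-monotonic time column in {path}")
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise DataError(f"non-uniform sampling in {path}")
        return PPGWaveform(
            samples=df["amplitude"].to_numpy(dtype=float),
            fs=1.0 / float(dt[0]),
            t0=float(t[0]),
        )
    if "amplitude" in cols:
        if fs is None:
            raise DataError(
                f"{path} has no time column and no '# fs=<Hz>' header line"
            )
        return PPGWaveform(samples=df["amplitude"].to_numpy(dtype=float), fs=fs)
    raise DataError(f"{path}: expected columns 'time,amplitude' or 'amplitude'")


def write_feature_table(path: str | Path, subjects: list[LabeledSubject]) -> None:
    subjects_to_frame(subjects).to_csv(path, index=False)


def read_feature_table(path: str | Path) -> list[LabeledSubject]:
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error surface
        raise DataError(f"cannot read feature table {path}: {exc}") from exc
    if df.empty:
        raise DataError(f"feature table {path} is empty")
    return subjects_from_frame(df)
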