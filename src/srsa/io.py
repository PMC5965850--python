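"""CSV schemas and validated readers/writers.

All tables are plain UTF-8 CSV with "." as the decimal separator:

* fixations — ``participant_id,trial_id,order,x,y,duration_ms``
* scores — ``participant_id,measure,score``
* signal (optional) — ``participant_id,trial_id,signal_percent``; when the
  file is absent every trial is assumed fully tracked (100%)
* state sequences — ``participant_id,trial_id,states`` with states
  dash-joined (``1-3-5``)
* results — Table-layout ``state_space,measure,r2,r2cv,gamma,alpha``

Readers fail with the file name and 1-based data line number of the first
malformed row.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SRSAError


class ParseError(SRSAError, ValueError):
    """A CSV row could not be parsed; message names file and line."""


def _require_columns(df: pd.DataFrame, cols: list, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")


def _numeric(df: pd.DataFrame, cols: list, path) -> pd.DataFrame:
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ParseError(
                f"{path}: line {line}: non-numeric value "
                f"{df.loc[bad.idxmax(), col]!r} in column {col!r}"
            )
        if coerced.isna().any():
            line = int(coerced.isna().idxmax()) + 2
            raise ParseError(f"{path}: line {line}: missing value in column {col!r}")
        df[col] = coerced
    return df


def read_fixations(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require_columns(
        df, ["participant_id", "trial_id", "order", "x", "y", "duration_ms"], path
    )
    df = _numeric(df, ["order", "x", "y", "duration_ms"], path)
    if (df["duration_ms"] <= 0).any():
        line = int((df["duration_ms"] <= 0).idxmax()) + 2
        raise ParseError(f"{path}: line {line}: duration_ms must be positive")
    return df


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str, "measure": str})
    _require_columns(df, ["participant_id", "measure", "score"], path)
    return _numeric(df, ["score"], path)


def read_signal(path=None) -> pd.DataFrame | None:
    """Read the optional signal table; None means 'assume 100% everywhere'."""
    if path is None or not Path(path).exists():
        return None
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require_columns(df, ["participant_id", "trial_id", "signal_percent"], path)
    df = _numeric(df, ["signal_percent"], path)
    if ((df["signal_percent"] < 0) | (df["signal_percent"] > 100)).any():
        raise ParseError(f"{path}: signal_percent must lie in [0, 100]")
    return df


def write_sr_matrix(path, matrix: np.ndarray, label: str = "") -> None:
    """Write a 5x5 SR/weight matrix as CSV (rows = receiver states)."""
    with open(path, "w") as fh:
        if label:
            fh.write(f"# {label}\n")
        np.savetxt(fh, np.asarray(matrix), delimiter=",", fmt="%.10g")


def read_sr_matrix(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", comments="#")


def write_results_table(path, rows: list) -> None:
    """Write the Table-layout results CSV."""
    pd.DataFrame(
        rows, columns=["state_space", "measure", "r2", "r2cv", "gamma", "alpha"]
    ).to_csv(path, index=False)
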