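"""CSV readers/writers for run tables and fermentation time series.

Thin validation layer over :mod:`pandas`: schemas are plain lists of column
names, errors name the offending row/column, and write -> read round-trips
are lossless (floats are serialized with shortest-round-trip repr).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

__all__ = ["read_csv_runs", "write_csv_runs", "read_timeseries"]


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")


def _require_numeric(df: pd.DataFrame, columns, path) -> pd.DataFrame:
    out = df.copy()
    for col in columns:
        converted = pd.to_numeric(out[col], errors="coerce")
        bad = converted.isna() & out[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(f"{path}: non-numeric value {out.loc[row, col]!r} "
                             f"in column {col!r}, row {row}")
        if converted.isna().any():
            row = int(converted.isna().idxmax())
            raise ValueError(f"{path}: missing value in column {col!r}, row {row}")
        out[col] = converted
    return out


def read_csv_runs(path, factor_columns, response_columns=()) -> pd.DataFrame:
    """Read a runs-by-columns table, validating schema and numeric content."""
    if os.path.getsize(path) == 0:
        raise ValueError(f"{path}: file is empty")
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    needed = list(factor_columns) + list(response_columns)
    _require_columns(df, needed, path)
    df = _require_numeric(df, needed, path)
    for col in response_columns:
        if (df[col] < 0).any():
            row = int((df[col] < 0).idxmax())
            raise ValueError(f"{path}: negative response {col!r} in row {row}")
    return df


def write_csv_runs(df: pd.DataFrame, path) -> None:
    """Write a runs table; numbers keep full (shortest round-trip) precision."""
    df.to_csv(path, index=False)


def read_timeseries(path, value_columns, time_column: str = "time") -> pd.DataFrame:
    """Read a fermentation time series; time must be strictly increasing."""
    df = read_csv_runs(path, [time_column], value_columns)
    t = df[time_column].to_numpy(float)
    if not np.all(np.diff(t) > 0):
        raise ValueError(f"{path}: column {time_column!r} must be strictly increasing")
    return df
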