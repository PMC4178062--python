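"""CSV schemas and report writing.

Specimen CSV header: ``specimen_id, group, river, sex, TL_mm, TM_g`` followed
by morphometric character columns (mm) and meristic count columns. Fatty-acid
CSV header: ``specimen_id, group, river, sex`` followed by one column per
fatty acid (percent); "ND" cells are read as exact zeros. Missing values are
only permitted in meristic columns. All files are UTF-8.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import SchemaError
from .synthetic import METADATA_COLUMNS

__all__ = [
    "read_specimen_csv",
    "write_specimen_csv",
    "read_fatty_acid_csv",
    "write_fatty_acid_csv",
    "write_report",
]

FA_METADATA = ["specimen_id", "group", "river", "sex"]


def _check_ids(df: pd.DataFrame, path) -> None:
    dupes = df["specimen_id"][df["specimen_id"].duplicated()]
    if len(dupes):
        raise SchemaError(
            f"{path}: duplicate specimen ids: {sorted(set(dupes))}"
        )


def read_specimen_csv(path, meristic_columns=None) -> pd.DataFrame:
    """Read a specimen table, enforcing the documented schema.

    Missing values are rejected except in *meristic_columns* (where a count
    may legitimately be unavailable).
    """
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {missing}")
    _check_ids(df, path)
    meristic_columns = set(meristic_columns or [])
    for col in df.columns:
        if col in meristic_columns:
            continue
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0])
            raise SchemaError(
                f"{path}: missing value in column {col!r} (row {row})"
            )
    return df


def write_specimen_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, encoding="utf-8")


def read_fatty_acid_csv(path) -> pd.DataFrame:
    """Read per-specimen fatty-acid percentages; "ND" becomes exact 0."""
    df = pd.read_csv(path, encoding="utf-8", dtype=str)
    missing = [c for c in FA_METADATA if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {missing}")
    _check_ids(df, path)
    for col in df.columns:
        if col in FA_METADATA:
            continue
        raw = df[col].fillna("ND").str.strip()
        nd = raw.str.upper() == "ND"
        vals = pd.to_numeric(raw.mask(nd, "0"), errors="raise").astype(float)
        vals[nd] = 0.0  # exact structural zero
        df[col] = vals
    return df


def write_fatty_acid_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, encoding="utf-8")


def write_report(bundle: dict, outdir) -> list[Path]:
    """Write a report bundle: DataFrames as CSV, mappings as sorted JSON.

    Returns the list of written paths. Output is deterministic: no
    timestamps, keys sorted, fixed float formatting left to pandas defaults.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, obj in bundle.items():
        if obj is None:
            continue
        if isinstance(obj, pd.DataFrame):
            path = outdir / f"{name}.csv"
            obj.to_csv(path, encoding="utf-8")
        elif isinstance(obj, pd.Series):
            path = outdir / f"{name}.csv"
            obj.to_frame().to_csv(path, encoding="utf-8")
        else:
            path = outdir / f"{name}.json"
            with open(path, "w", encoding="utf-8") as fh:
                json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
                fh.write("\n")
        written.append(path)
    return written


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if hasattr(obj, "__dataclass_fields__"):
        return {k: getattr(obj, k) for k in obj.__dataclass_fields__}
    raise TypeError(f"cannot serialize {type(obj)!r}")
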