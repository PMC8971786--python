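"""Reading and writing the pipeline's table formats.

Clonotype tables travel as AIRR Rearrangement TSV (``sequence_id``,
``junction_aa``, ``duplicate_count`` at minimum) or as a minimal two-column
CSV (``clonotype_id,count``). Cell, core and clinical tables are headered
CSV. Every CSV the pipeline writes gets a JSON sidecar declaring its column
schema (``<name>.schema.json``); ``read_table`` validates against the sidecar
when present.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import pandas as pd

from .exceptions import FormatError

__all__ = [
    "read_airr",
    "write_airr",
    "read_clonotype_csv",
    "write_clonotype_csv",
    "write_table",
    "read_table",
    "sha256_of",
]

AIRR_COUNT_COLUMNS = ("duplicate_count", "count", "templates")
AIRR_JUNCTION_COLUMNS = ("junction_aa", "junction", "amino_acid", "cdr3_amino_acid")


def read_airr(path: str | Path) -> pd.DataFrame:
    """Read an AIRR Rearrangement TSV into a clonotype table.

    Rows sharing a junction are aggregated into one clonotype with summed
    counts (the clonotype id is the first sequence_id of the group, or the
    junction itself when no id column exists). Rows with nonpositive counts
    are dropped with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sequence_id": str})
    count_col = next((c for c in AIRR_COUNT_COLUMNS if c in df.columns), None)
    if count_col is None:
        raise FormatError(
            f"{path.name}: no count column (looked for {AIRR_COUNT_COLUMNS}); "
            f"columns present: {list(df.columns)}"
        )
    junction_col = next((c for c in AIRR_JUNCTION_COLUMNS if c in df.columns), None)
    if junction_col is None:
        raise FormatError(
            f"{path.name}: no junction column (looked for {AIRR_JUNCTION_COLUMNS}); "
            f"columns present: {list(df.columns)}"
        )
    bad = df[count_col] <= 0
    if bad.any():
        warnings.warn(
            f"{path.name}: dropping {int(bad.sum())} rows with nonpositive counts",
            UserWarning,
            stacklevel=2,
        )
        df = df[~bad]
    if "sequence_id" not in df.columns:
        df = df.assign(sequence_id=df[junction_col])
    grouped = (
        df.groupby(junction_col, sort=False)
        .agg(clonotype_id=("sequence_id", "first"), count=(count_col, "sum"))
        .reset_index()
        .rename(columns={junction_col: "junction_aa"})
    )
    return grouped[["clonotype_id", "junction_aa", "count"]].astype({"count": int})


def write_airr(rep: pd.DataFrame, path: str | Path) -> Path:
    """Write a clonotype table as AIRR Rearrangement TSV."""
    path = Path(path)
    out = pd.DataFrame(
        {
            "sequence_id": rep["clonotype_id"],
            "junction_aa": rep.get("junction_aa", rep["clonotype_id"]),
            "duplicate_count": rep["count"].astype(int),
        }
    )
    out.to_csv(path, sep="\t", index=False)
    return path


def read_clonotype_csv(path: str | Path) -> pd.DataFrame:
    """Read the minimal two-column ``clonotype_id,count`` CSV."""
    path = Path(path)
    df = pd.read_csv(path)
    if "clonotype_id" not in df.columns or "count" not in df.columns:
        raise FormatError(
            f"{path.name}: expected columns clonotype_id,count; got {list(df.columns)}"
        )
    bad = df["count"] <= 0
    if bad.any():
        warnings.warn(
            f"{path.name}: dropping {int(bad.sum())} rows with nonpositive counts",
            UserWarning,
            stacklevel=2,
        )
        df = df[~bad]
    return df.reset_index(drop=True).astype({"count": int})


def write_clonotype_csv(rep: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = ["clonotype_id", "count"]
    if "junction_aa" in rep.columns:
        cols = ["clonotype_id", "junction_aa", "count"]
    rep[cols].to_csv(path, index=False)
    return path


def _schema_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".schema.json")


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a headered CSV plus its JSON column-schema sidecar."""
    path = Path(path)
    df.to_csv(path, index=False)
    schema = {"columns": [{"name": c, "dtype": str(df[c].dtype)} for c in df.columns]}
    _schema_path(path).write_text(json.dumps(schema, indent=1) + "\n")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a headered CSV, validating column names against its sidecar schema
    when one exists."""
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = _schema_path(path)
    if sidecar.exists():
        schema = json.loads(sidecar.read_text())
        expected = [c["name"] for c in schema.get("columns", [])]
        if list(df.columns) != expected:
            raise FormatError(
                f"{path.name}: columns {list(df.columns)} do not match schema {expected}"
            )
    return df


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
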