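"""Tab-separated table I/O with provenance comment headers.

Every table written by the pipeline starts with ``#``-prefixed comment
lines recording at least the generator seed and configuration hash, so
downstream outputs can be audited back to the run that produced them.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["write_table", "read_table", "validate_columns",
           "COHORT_COLUMNS", "GEOMETRY_COLUMNS"]

COHORT_COLUMNS = ("participant_id", "cm_score", "at_score", "bmi", "crp",
                  "age", "sex", "ses", "site")
GEOMETRY_COLUMNS = ("region_id", "structure_class", "x", "y", "z")


def validate_columns(df: pd.DataFrame, required, table_name: str) -> pd.DataFrame:
    """Schema check: raise naming every missing column."""
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{table_name} table is missing required columns: {missing}")
    return df


def write_table(df: pd.DataFrame, path, meta: dict | None = None, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, index_col=None):
    """Read a TSV written by :func:`write_table`; returns (frame, meta)."""
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, value = body.split("=", 1)
                meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", index_col=index_col)
    return df, meta
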