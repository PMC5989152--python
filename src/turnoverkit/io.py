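"""Readers and writers for the pipeline's tab-separated tables.

All tables are plain TSV with required headers; times are hours, ratios are
linear (log2 values are computed in memory), and every reader validates its
schema and rejects malformed rows with their row numbers (1-based, counting
data rows below the header).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A table is missing required columns."""


class RowError(ValueError):
    """A table contains malformed rows."""


PEPTIDE_COLUMNS = [
    "peptide_id", "protein_id", "condition", "replicate", "time_h",
    "channel", "ratio", "intensity",
]
_PEPTIDE_KEY = ["peptide_id", "condition", "replicate", "time_h", "channel"]


def _require(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_peptide_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a peptide-level SILAC ratio table."""
    df = pd.read_csv(path, sep="\t")
    _require(df, PEPTIDE_COLUMNS, path)
    ratio = pd.to_numeric(df["ratio"], errors="coerce")
    bad = df.index[~(ratio > 0)] + 1
    if len(bad):
        raise RowError(f"{path}: non-positive or non-numeric ratio on row(s) "
                       f"{list(bad[:10])}")
    known = df["channel"].isin(["M/L", "H/L"])
    if not known.all():
        bad = df.index[~known] + 1
        raise RowError(f"{path}: unknown channel label on row(s) {list(bad[:10])}")
    dup = df.duplicated(subset=_PEPTIDE_KEY)
    if dup.any():
        rows = (df.index[dup] + 1).tolist()
        raise RowError(f"{path}: duplicate (peptide, condition, replicate, time, "
                       f"channel) on row(s) {rows[:10]}")
    df["ratio"] = ratio
    df["time_h"] = pd.to_numeric(df["time_h"])
    df["replicate"] = pd.to_numeric(df["replicate"], downcast="integer")
    return df[PEPTIDE_COLUMNS]


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a TSV with a stable float format (deterministic reruns)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_two_column_map(path: str | Path, key: str, value: str) -> dict[str, set[str]]:
    """Two-column TSV (e.g. term->protein or complex->protein) as a dict."""
    df = pd.read_csv(path, sep="\t")
    _require(df, [key, value], path)
    out: dict[str, set[str]] = {}
    for k, v in zip(df[key], df[value]):
        out.setdefault(str(k), set()).add(str(v))
    return out


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene-set dialect: term <tab> description <tab> members..."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise RowError(f"{path}: row {i}: GMT rows need >= 3 fields")
            out[parts[0]] = set(parts[2:])
    return out


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Genes x patients expression matrix (first column = gene id)."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene":
        raise SchemaError(f"{path}: first column must be 'gene'")
    return df.set_index("gene")


def read_survival(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, ["patient_id", "time_years", "event"], path)
    bad = df.index[~(pd.to_numeric(df["time_years"], errors="coerce") > 0)] + 1
    if len(bad):
        raise RowError(f"{path}: non-positive survival time on row(s) {list(bad[:10])}")
    if not df["event"].isin([0, 1]).all():
        bad = (df.index[~df["event"].isin([0, 1])] + 1).tolist()
        raise RowError(f"{path}: event indicator must be 0/1, row(s) {bad[:10]}")
    return df
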