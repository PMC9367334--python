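"""TSV input/output with an explicit missing-value dialect.

All tables are tab-separated text. In abundance files an empty field means
*not detected* (missing), never zero; identifiers must be unique; numeric
cells must parse as numbers. Parse failures report the offending line.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ffpemarkers.abundance import AbundanceMatrix

__all__ = ["ParseError", "read_abundance", "write_abundance", "read_table", "write_table"]


class ParseError(ValueError):
    """Malformed tabular input; carries the 1-based line number when known."""


def read_abundance(path, state: str = "raw") -> AbundanceMatrix:
    """Read a protein x sample abundance TSV (first column ``protein_id``)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "protein_id":
        raise ParseError(f"{path}: first column must be 'protein_id', got {df.columns[0]!r} (line 1)")
    if df["protein_id"].duplicated().any():
        dup = df.loc[df["protein_id"].duplicated(), "protein_id"].iloc[0]
        line = int(df.index[df["protein_id"] == dup][1]) + 2
        raise ParseError(f"{path}: duplicate protein id {dup!r} (line {line})")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ParseError(f"{path}: duplicate sample id {dup!r} (line 1)")
    df = df.set_index("protein_id")
    values = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        raw = df[col].to_numpy()
        empty = raw == ""
        try:
            nums = pd.to_numeric(pd.Series(raw).replace("", None)).to_numpy(dtype=float)
        except (ValueError, TypeError):
            for i, (v, e) in enumerate(zip(raw, empty)):
                if not e:
                    try:
                        float(v)
                    except ValueError:
                        raise ParseError(
                            f"{path}: non-numeric cell {v!r} in column {col!r} (line {i + 2})"
                        ) from None
            raise
        values[col] = nums
    return AbundanceMatrix(values=values, state=state)


def write_abundance(m: AbundanceMatrix, path) -> None:
    """Write an abundance matrix; missing entries become empty fields."""
    out = m.values.copy()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t", na_rep="", lineterminator="\n", float_format="%.10g")


def read_table(path, index_col: str) -> pd.DataFrame:
    """Read a generic TSV keyed by ``index_col`` (annotation, truth, results)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if index_col not in df.columns:
        raise ParseError(f"{path}: missing key column {index_col!r} (line 1)")
    if df[index_col].duplicated().any():
        dup = df.loc[df[index_col].duplicated(), index_col].iloc[0]
        raise ParseError(f"{path}: duplicate {index_col} {dup!r}")
    return df.set_index(index_col)


def write_table(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", na_rep="", lineterminator="\n", index_label=index_label)
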