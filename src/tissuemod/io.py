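"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression tables are TSV with a header row and the gene id in the first
column; floats are written with 17 significant digits so a write/read
round-trip is bit-stable.  BED intervals are 0-based half-open; variant
tables are 1-based.  GMT follows the usual ``name<TAB>description<TAB>genes``
layout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import META_COLUMNS, DataError, ExpressionDataset

FLOAT_FORMAT = "%.17g"

VARIANT_COLUMNS = ("rsID", "chrom", "pos_1based", "trait")


class ParseError(DataError):
    """Raised for malformed input files; the message names the location."""


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a gene x sample TSV into a float DataFrame.

    Raises :class:`ParseError` for duplicate gene ids, ragged rows or
    non-numeric cells, naming the offending location.  CRLF and LF line
    endings are both accepted (pandas normalises them).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate gene id(s) {dupes}")
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        raise ParseError(f"{path}: ragged or empty cell in row {gene!r}")
    try:
        out = df.astype(float)
    except ValueError:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            if bad.any():
                gene = df.index[bad][0]
                raise ParseError(
                    f"{path}: non-numeric cell at gene {gene!r}, sample {col!r}: "
                    f"{df.loc[gene, col]!r}"
                ) from None
        raise
    return out


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="gene")


def read_metadata_tsv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ParseError(f"{path}: metadata lacks columns {missing}")
    return meta


def write_metadata_tsv(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="sample_id")


def read_dataset(expr_path, meta_path, name: str = "") -> ExpressionDataset:
    return ExpressionDataset(
        read_expression_tsv(expr_path), read_metadata_tsv(meta_path), name=name
    )


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """Generic TSV writer used for every derived result table."""
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index, na_rep="NA")


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file into columns chrom/start/end/name (0-based half-open)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED line has <3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer BED coordinates") from None
            name = parts[3] if len(parts) > 3 else f"{parts[0]}:{start}-{end}"
            rows.append((parts[0], start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_variants_tsv(path) -> pd.DataFrame:
    """Read a variant TSV with columns rsID, chrom, pos_1based, trait."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: variant table lacks columns {missing}")
    try:
        pos = df["pos_1based"].astype(int)
    except ValueError:
        bad = pd.to_numeric(df["pos_1based"], errors="coerce").isna()
        lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise ParseError(
            f"{path}:{lineno}: malformed position {df['pos_1based'][bad].iloc[0]!r}"
        ) from None
    out = df.copy()
    out["pos_1based"] = pos
    if (out["pos_1based"] < 1).any():
        lineno = int(np.flatnonzero((out["pos_1based"] < 1).to_numpy())[0]) + 2
        raise ParseError(f"{path}:{lineno}: position must be >= 1")
    return out


def write_variants_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict:
    """Read a GMT file into ``{set_name: set(genes)}``."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs name, description, genes")
            sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: dict, path, description: str = "tissuemod") -> None:
    with open(path, "w") as fh:
        for name in sets:
            genes = sorted(sets[name])
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
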