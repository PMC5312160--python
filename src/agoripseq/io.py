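"""Readers and writers for the tabular formats used by the pipeline.

All files are plain TSV: a genes x libraries count matrix with a
``gene_id`` column, a sample sheet (library_id, treatment, ip,
replicate), per-contrast result tables and target-call tables.  Readers
validate aggressively and report offending coordinates.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .glm import validate_design
from .normalize import validate_counts

__all__ = [
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_table",
    "write_table",
]


def read_counts(path) -> pd.DataFrame:
    """Read a genes x libraries count TSV (first column ``gene_id``)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene_id":
        raise ValueError(f"{path}: first column must be 'gene_id', got {df.columns[0]!r}")
    df = df.set_index("gene_id")
    for col in df.columns:
        series = pd.to_numeric(df[col], errors="coerce")
        if series.isna().any():
            row = df.index[series.isna().to_numpy().argmax()]
            raise ValueError(f"{path}: non-numeric count at gene {row!r}, library {col!r}")
        df[col] = series
    return validate_counts(df)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read and validate a sample sheet TSV (library_id, treatment, ip, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "replicate" in df.columns:
        df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)
    return validate_design(df)


def write_sample_sheet(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    """Read a generic TSV result table (contrast results, truth, tissue)."""
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, float_format: str = "%.10g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def join_counts_design(counts: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Check the sample sheet against the count matrix and align its order."""
    missing = [l for l in design["library_id"] if l not in counts.columns]
    if missing:
        raise ValueError(f"libraries in sample sheet absent from count matrix: {missing}")
    extra = [c for c in counts.columns if c not in set(design["library_id"])]
    if extra:
        raise ValueError(f"libraries in count matrix absent from sample sheet: {extra}")
    return counts.loc[:, design["library_id"].tolist()]
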