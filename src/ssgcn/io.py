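"""Readers and writers for the pipeline's delimited table formats.

Expression matrices are genes x samples tables with a header row of sample
IDs and the gene ID in the first column; tab and comma dialects are
auto-detected. Annotation tables are BED-like with 1-based inclusive
coordinates and chromosome names normalized so "chr17" and "17" refer to
the same key. All floats are written with 17 significant digits so a
write/read round trip reproduces values to better than 1e-12.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EdgeList, ExpressionMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "read_clinical",
    "write_clinical",
    "read_edge_list",
    "write_edge_list",
]

FLOAT_FORMAT = "%.17g"

ANNOTATION_REQUIRED = ["gene_id", "chromosome", "cytoband", "start", "end"]


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_expression(path, stage: str = "raw") -> ExpressionMatrix:
    """Read a delimited genes x samples matrix with validation."""
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene IDs {dup}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample IDs {dup}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression values") from exc
    if (values.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative expression values")
    if stage == "raw":
        arr = values.to_numpy()
        if np.allclose(arr, np.round(arr)):
            values = values.round().astype(np.int64)
    return ExpressionMatrix(values, stage=stage)


def write_expression(expr, path) -> None:
    df = expr.values if isinstance(expr, ExpressionMatrix) else expr
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def normalize_chromosome(name: str) -> str:
    """Unify chromosome naming: strip a leading 'chr' prefix."""
    s = str(name).strip()
    return s[3:] if s.lower().startswith("chr") else s


def read_annotation(path) -> pd.DataFrame:
    """Read a gene annotation table (1-based inclusive coordinates)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path))
    missing = [c for c in ANNOTATION_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation columns {missing}")
    df["gene_id"] = df["gene_id"].astype(str)
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"{path}: duplicate gene IDs {dup}")
    df["chromosome"] = df["chromosome"].map(normalize_chromosome)
    df["cytoband"] = df["cytoband"].astype(str)
    bad = df["start"] > df["end"]
    if bad.any():
        raise ValueError(
            f"{path}: start > end for genes {df.loc[bad, 'gene_id'].tolist()}"
        )
    return df.set_index("gene_id")


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical table (sample_id, time_days, event[, group, subtype])."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path))
    required = {"sample_id", "time_days", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing clinical columns {sorted(missing)}")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample IDs")
    return df


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_edge_list(path, provenance: str = "aggregated") -> EdgeList:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    return EdgeList(df, provenance=provenance)


def write_edge_list(edges, path) -> None:
    df = edges.df if isinstance(edges, EdgeList) else edges
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
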