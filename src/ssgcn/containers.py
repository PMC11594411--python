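"""Shared in-memory containers for expression matrices and edge lists.

An :class:`ExpressionMatrix` wraps a genes x samples :class:`pandas.DataFrame`
and carries a processing-stage tag (``raw`` -> ``filtered`` -> ``normalized``)
so downstream stages can enforce their preconditions.  An :class:`EdgeList`
wraps a three-column frame of weighted, undirected gene pairs together with a
provenance tag saying which kind of network it came from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "EdgeList", "STAGES", "PROVENANCES"]

STAGES = ("raw", "filtered", "normalized")
PROVENANCES = ("aggregated", "leave_one_out", "single_sample")


class ExpressionMatrix:
    """Genes x samples numeric matrix with unique identifiers and a stage tag.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID with sample IDs as columns.
    stage
        One of ``raw`` (integer counts), ``filtered`` or ``normalized``.
    """

    def __init__(self, values: pd.DataFrame, stage: str = "raw"):
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated gene IDs: {dup}")
        if values.columns.duplicated().any():
            dup = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicated sample IDs: {dup}")
        arr = values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")
        if stage == "raw" and not np.allclose(arr, np.round(arr)):
            raise ValueError("raw counts must be integers")
        self.values = values.copy()
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        self.values.index.name = "gene_id"
        self.stage = stage

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_stage(self, stage: str) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values, stage=stage)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples, "
            f"stage={self.stage!r})"
        )


@dataclass
class EdgeList:
    """Weighted undirected gene-pair list.

    ``df`` has columns ``gene_a``, ``gene_b``, ``weight`` with
    ``gene_a < gene_b`` lexicographically; no self-loops, no duplicates.
    """

    df: pd.DataFrame
    provenance: str = "aggregated"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        required = ["gene_a", "gene_b", "weight"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"edge list missing columns: {missing}")
        df = self.df[required].copy()
        df["gene_a"] = df["gene_a"].astype(str)
        df["gene_b"] = df["gene_b"].astype(str)
        swap = df["gene_a"] > df["gene_b"]
        if swap.any():
            a = df.loc[swap, "gene_b"].copy()
            df.loc[swap, "gene_b"] = df.loc[swap, "gene_a"]
            df.loc[swap, "gene_a"] = a
        if (df["gene_a"] == df["gene_b"]).any():
            raise ValueError("self-loops are not allowed")
        if df.duplicated(subset=["gene_a", "gene_b"]).any():
            raise ValueError("duplicate gene pairs are not allowed")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def pairs(self) -> set[tuple[str, str]]:
        """Edges as a set of (gene_a, gene_b) tuples with gene_a < gene_b."""
        return set(zip(self.df["gene_a"], self.df["gene_b"]))

    def genes(self) -> set[str]:
        return set(self.df["gene_a"]) | set(self.df["gene_b"])


def as_edge_frame(edges) -> pd.DataFrame:
    """Accept an EdgeList or a bare DataFrame and return the frame."""
    if isinstance(edges, EdgeList):
        return edges.df
    return edges
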