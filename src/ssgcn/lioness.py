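"""LIONESS single-sample networks from any cohort edge-scoring function.

For a cohort of N samples and an edge score e computed on a set of samples,
the network of sample q is

    e(q) = N * (e(alpha) - e(alpha - q)) + e(alpha - q)
         = N * e(alpha) - (N - 1) * e(alpha - q)

where e(alpha) uses all samples and e(alpha - q) leaves sample q out.  The
score function is pluggable: mutual information is the default, Pearson
correlation and a linear per-sample-mean stub are provided (the stub makes
the exact algebraic identity mean_q e(q) = e(alpha) testable).

Edge scores are held as condensed upper-triangle vectors in the row order of
the cohort gene list. The cohort aggregated score is computed once and
reused for every sample; each leave-one-out network is recomputed from
scratch (O(N * G^2) overall for histogram MI).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .containers import EdgeList, ExpressionMatrix
from .mi import TOP_K_DEFAULT, build_mi_matrix

__all__ = [
    "SampleNetwork",
    "mi_score",
    "pearson_score",
    "linear_mean_product_score",
    "lioness_scores",
    "all_sample_networks",
    "top_k_abs",
]

ScoreFn = Callable[[pd.DataFrame], np.ndarray]


def _frame(expr) -> pd.DataFrame:
    return expr.values if isinstance(expr, ExpressionMatrix) else expr


def _condense(matrix: np.ndarray) -> np.ndarray:
    iu, ju = np.triu_indices(matrix.shape[0], 1)
    return matrix[iu, ju]


@dataclass
class SampleNetwork:
    """Single-sample network: condensed edge weights over the cohort genes.

    Weights may be negative; ranking for truncation uses absolute values
    while the signed weight is preserved in outputs.
    """

    sample_id: str
    gene_ids: list[str]
    weights: np.ndarray
    n_cohort: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        expected = len(self.gene_ids) * (len(self.gene_ids) - 1) // 2
        if self.weights.shape != (expected,):
            raise ValueError("condensed weight vector has wrong length")

    def edge_list(self) -> EdgeList:
        iu, ju = np.triu_indices(len(self.gene_ids), 1)
        genes = np.asarray(self.gene_ids, dtype=object)
        df = pd.DataFrame(
            {"gene_a": genes[iu], "gene_b": genes[ju], "weight": self.weights}
        )
        return EdgeList(df, provenance="single_sample")


def mi_score(bins: int | None = None, miller_madow: bool = False) -> ScoreFn:
    """MI edge score over a cohort (condensed vector)."""

    def fn(df: pd.DataFrame) -> np.ndarray:
        return _condense(build_mi_matrix(df, bins=bins, miller_madow=miller_madow).matrix)

    return fn


def pearson_score(df: pd.DataFrame) -> np.ndarray:
    """Pearson correlation edge score (condensed vector)."""
    values = df.to_numpy(dtype=float)
    sd = values.std(axis=1)
    # relative tolerance: a constant profile can have sd ~ 1e-17 from rounding
    flat = sd <= 1e-12 * (np.abs(values).max(axis=1) + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr[~np.isfinite(corr)] = 0.0
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    return _condense(corr)


def linear_mean_product_score(df: pd.DataFrame) -> np.ndarray:
    """Per-edge mean over samples of x_i * x_j: linear in the sample set."""
    values = df.to_numpy(dtype=float)
    return _condense(values @ values.T / values.shape[1])


def lioness_scores(
    expr,
    score_fn: ScoreFn,
    q: str,
    e_alpha: np.ndarray | None = None,
) -> SampleNetwork:
    """Single-sample network of sample ``q`` via the leave-one-out equation.

    ``e_alpha`` may be supplied to reuse a cached aggregated score.
    """
    df = _frame(expr)
    n = df.shape[1]
    if n < 3:
        raise ValueError("LIONESS needs at least 3 samples")
    if q not in df.columns:
        raise KeyError(f"sample {q!r} not in cohort")
    if e_alpha is None:
        e_alpha = score_fn(df)
    e_loo = score_fn(df.drop(columns=[q]))
    weights = n * e_alpha - (n - 1) * e_loo
    return SampleNetwork(
        sample_id=str(q),
        gene_ids=list(df.index),
        weights=weights,
        n_cohort=n,
        meta={"e_alpha": e_alpha, "e_leave_one_out": e_loo},
    )


def all_sample_networks(expr, score_fn: ScoreFn) -> list[SampleNetwork]:
    """One single-sample network per cohort sample (order follows columns).

    The output of each network is independent of evaluation order; the
    aggregated score is computed once and shared.
    """
    df = _frame(expr)
    if df.shape[1] < 3:
        raise ValueError("LIONESS needs at least 3 samples")
    e_alpha = score_fn(df)
    return [lioness_scores(df, score_fn, q, e_alpha=e_alpha) for q in df.columns]


def top_k_abs(net: SampleNetwork, k: int = TOP_K_DEFAULT) -> EdgeList:
    """Strongest k edges of a single-sample network by absolute weight.

    Ties break lexicographically by gene pair; the signed weight is kept.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    edges = net.edge_list()
    df = edges.df.copy()
    df["_abs"] = df["weight"].abs()
    df = df.sort_values(
        ["_abs", "gene_a", "gene_b"], ascending=[False, True, True], kind="mergesort"
    ).head(k)
    out = EdgeList(
        df.drop(columns="_abs").reset_index(drop=True), provenance="single_sample"
    )
    out.meta.update({"sample_id": net.sample_id, "n_cohort": net.n_cohort, "k": k})
    return out
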