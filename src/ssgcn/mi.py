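"""Mutual-information co-expression network inference.

The estimator is deliberately transparent: each expression profile is
discretized into equal-frequency bins by rank (ties broken by original
sample index), and MI in nats is the plug-in estimate from the joint
histogram, optionally Miller-Madow bias-corrected and floored at zero.
All gene pairs of a cohort are evaluated; an optional data-processing-
inequality (DPI) pruning step removes the weakest edge of fully connected
triples, and networks are truncated to the strongest k edges with a
deterministic lexicographic tie-break.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EdgeList, ExpressionMatrix

__all__ = [
    "MIMatrix",
    "default_bins",
    "mutual_information",
    "build_mi_matrix",
    "dpi_prune",
    "top_k_edges",
    "candidate_pair_count",
]

log = logging.getLogger(__name__)

TOP_K_DEFAULT = 10_000


@dataclass
class MIMatrix:
    """Symmetric non-negative MI matrix (nats) with estimator descriptor."""

    gene_ids: list[str]
    matrix: np.ndarray
    descriptor: dict = field(default_factory=dict)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.gene_ids), len(self.gene_ids)):
            raise ValueError("matrix shape does not match gene_ids")
        if not np.allclose(m, m.T):
            raise ValueError("MI matrix must be symmetric")
        if (m < 0).any():
            raise ValueError("MI values must be non-negative")
        self.matrix = m


def candidate_pair_count(n_genes: int) -> int:
    """Number of unordered gene pairs, C(n_genes, 2)."""
    return n_genes * (n_genes - 1) // 2


def default_bins(n: int) -> int:
    """Default bin count: max(2, floor(n^(1/3)))."""
    return max(2, int(np.floor(np.cbrt(n) + 1e-9)))


def _bin_codes(values: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency bin codes per row; constant rows collapse to bin 0."""
    g, n = values.shape
    codes = np.empty((g, n), dtype=np.int64)
    ranks = np.arange(n) * bins // n
    for i in range(g):
        row = values[i]
        if np.ptp(row) == 0:
            warnings.warn(
                "constant expression profile: single occupied bin, MI = 0",
                stacklevel=3,
            )
            codes[i] = 0
        else:
            order = np.argsort(row, kind="stable")  # ties -> original index
            codes[i, order] = ranks
    return codes


def mutual_information(
    x: np.ndarray,
    y: np.ndarray,
    bins: int | None = None,
    miller_madow: bool = False,
) -> float:
    """Plug-in MI (nats) between two profiles via equal-frequency binning."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 8:
        raise ValueError("need at least 8 observations")
    if bins is None:
        bins = default_bins(n)
    if bins < 2:
        raise ValueError("bins must be >= 2")
    cx, cy = _bin_codes(np.vstack([x, y]), bins)
    joint = np.zeros((bins, bins))
    np.add.at(joint, (cx, cy), 1.0)
    return _mi_from_joint(joint, n, miller_madow)


def _mi_from_joint(joint: np.ndarray, n: int, miller_madow: bool) -> float:
    p = joint / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        hx = -np.sum(np.where(px > 0, px * np.log(px), 0.0))
        hy = -np.sum(np.where(py > 0, py * np.log(py), 0.0))
        hxy = -np.sum(np.where(p > 0, p * np.log(p), 0.0))
    mi = hx + hy - hxy
    if miller_madow:
        mi += ((joint > 0).sum() - (px > 0).sum() - (py > 0).sum() + 1) / (2.0 * n)
    return float(max(mi, 0.0))


def _pairwise_mi(codes: np.ndarray, bins: int, miller_madow: bool) -> np.ndarray:
    """All-pairs MI from bin codes via one-hot joint-count matrix products."""
    g, n = codes.shape
    onehot = (codes[:, :, None] == np.arange(bins)[None, None, :]).astype(np.float64)
    flat = onehot.transpose(0, 2, 1).reshape(g * bins, n)
    joint = (flat @ flat.T).reshape(g, bins, g, bins).transpose(0, 2, 1, 3)
    p = joint / n
    with np.errstate(divide="ignore", invalid="ignore"):
        hxy = -np.sum(np.where(p > 0, p * np.log(p), 0.0), axis=(2, 3))
    marg = onehot.sum(axis=1) / n  # g x bins
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.sum(np.where(marg > 0, marg * np.log(marg), 0.0), axis=1)
    mi = h[:, None] + h[None, :] - hxy
    if miller_madow:
        occ_joint = (joint > 0).sum(axis=(2, 3))
        occ = (marg > 0).sum(axis=1)
        mi += (occ_joint - occ[:, None] - occ[None, :] + 1) / (2.0 * n)
    np.fill_diagonal(mi, 0.0)
    return np.maximum(mi, 0.0)


def build_mi_matrix(
    expr,
    bins: int | None = None,
    miller_madow: bool = False,
) -> MIMatrix:
    """MI for all gene pairs of a cohort matrix (sample-order invariant)."""
    df = expr.values if isinstance(expr, ExpressionMatrix) else expr
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("expression matrix contains non-finite values")
    g, n = values.shape
    if g < 2:
        raise ValueError("need at least 2 genes")
    if bins is None:
        bins = default_bins(n)
    n_pairs = candidate_pair_count(g)
    log.info("build_mi_matrix: evaluating %d candidate pairs (%d genes)", n_pairs, g)
    # bin on sample-sorted columns so the estimate cannot depend on column order
    order = np.argsort(np.asarray(df.columns, dtype=str), kind="stable")
    codes = _bin_codes(values[:, order], bins)
    mi = _pairwise_mi(codes, bins, miller_madow)
    return MIMatrix(
        gene_ids=list(df.index),
        matrix=mi,
        descriptor={"bins": bins, "miller_madow": miller_madow, "n_samples": n},
    )


def dpi_prune(mi: MIMatrix, tolerance: float = 0.0) -> MIMatrix:
    """Data-processing-inequality pruning of likely indirect edges.

    For every triple (i, j, k) with all three MI values positive, edge
    (i, j) is removed if MI(i,j) < min(MI(i,k), MI(j,k)) * (1 - tolerance).
    All removals are decided on the input matrix and applied together.
    """
    if not 0.0 <= tolerance <= 1.0:
        raise ValueError("tolerance must be in [0, 1]")
    m = mi.matrix.copy()
    np.fill_diagonal(m, 0.0)
    g = m.shape[0]
    best = np.zeros_like(m)
    for i in range(g):
        # min(M[i,k], M[j,k]) over k, maximized; zero rows never dominate
        best[i] = np.minimum(m[i][None, :], m).max(axis=1)
    remove = (m > 0) & (m < best * (1.0 - tolerance))
    out = m.copy()
    out[remove | remove.T] = 0.0
    desc = dict(mi.descriptor)
    desc["dpi_tolerance"] = tolerance
    return MIMatrix(gene_ids=mi.gene_ids, matrix=out, descriptor=desc)


def _lex_ranks(gene_ids: list[str]) -> np.ndarray:
    order = sorted(range(len(gene_ids)), key=lambda i: gene_ids[i])
    ranks = np.empty(len(gene_ids), dtype=np.int64)
    for r, i in enumerate(order):
        ranks[i] = r
    return ranks


def top_k_edges(source, k: int = TOP_K_DEFAULT, provenance: str = "aggregated") -> EdgeList:
    """Strongest k edges, ties at the cutoff broken by lexicographic pair.

    ``source`` is an :class:`MIMatrix` or an :class:`EdgeList`/DataFrame.
    If fewer than k pairs exist, all are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(source, MIMatrix):
        gene_ids = np.asarray(source.gene_ids, dtype=object)
        iu, ju = np.triu_indices(len(gene_ids), 1)
        weights = source.matrix[iu, ju]
        lex = _lex_ranks(source.gene_ids)
        a_lex, b_lex = lex[iu], lex[ju]
        swap = a_lex > b_lex
        a_lex[swap], b_lex[swap] = b_lex[swap], a_lex[swap]
        iu2 = np.where(swap, ju, iu)
        ju2 = np.where(swap, iu, ju)
        order = np.lexsort((b_lex, a_lex, -weights))[: min(k, weights.size)]
        df = pd.DataFrame(
            {
                "gene_a": gene_ids[iu2[order]],
                "gene_b": gene_ids[ju2[order]],
                "weight": weights[order],
            }
        )
        total = weights.size
    else:
        src = source.df if isinstance(source, EdgeList) else source
        a = src["gene_a"].to_numpy(dtype=object)
        b = src["gene_b"].to_numpy(dtype=object)
        w = src["weight"].to_numpy(dtype=float)
        uniq = {g: r for r, g in enumerate(sorted(set(a) | set(b)))}
        a_lex = np.array([uniq[g] for g in a])
        b_lex = np.array([uniq[g] for g in b])
        order = np.lexsort((b_lex, a_lex, -w))[: min(k, w.size)]
        df = src.iloc[order][["gene_a", "gene_b", "weight"]].reset_index(drop=True)
        total = w.size
    if total < k:
        warnings.warn(
            f"requested top {k} edges but only {total} pairs exist; returning all",
            stacklevel=2,
        )
    return EdgeList(df, provenance=provenance)
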