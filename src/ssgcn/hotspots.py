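"""Genomic localization of network edges: CIS/TRANS and hotspot tables.

Every edge falls in exactly one of three categories: both genes in the same
cytoband (INTRA_CYTOBAND), same chromosome but different cytobands
(INTER_CYTOBAND_CIS), or different chromosomes (TRANS); CIS = the first two.
Region hotspot tables count intra-region edges and normalize by the number
of possible pairs C(n_region_genes, 2) among the network's gene universe,
so proportions are bounded in [0, 1] and equal 1 exactly when the region's
genes form a clique. Cytoband identity is always the (chromosome, cytoband)
pair; bare cytoband strings are display-only.
"""

from __future__ import annotations

import logging
import warnings
from enum import Enum

import numpy as np
import pandas as pd

from .containers import EdgeList, as_edge_frame

__all__ = [
    "EdgeCategory",
    "classify_edge",
    "classify_edges",
    "cis_trans_summary",
    "region_hotspots",
    "per_sample_argmax_regions",
]

log = logging.getLogger(__name__)


class EdgeCategory(str, Enum):
    INTRA_CYTOBAND = "INTRA_CYTOBAND"
    INTER_CYTOBAND_CIS = "INTER_CYTOBAND_CIS"
    TRANS = "TRANS"

    @property
    def is_cis(self) -> bool:
        return self is not EdgeCategory.TRANS


def _check_annotated(genes, annotation: pd.DataFrame) -> None:
    missing = sorted(set(genes) - set(annotation.index))
    if missing:
        raise ValueError(f"genes missing from annotation: {missing}")


def classify_edge(gene_a: str, gene_b: str, annotation: pd.DataFrame) -> EdgeCategory:
    """Category of a single edge from the two genes' annotation."""
    _check_annotated([gene_a, gene_b], annotation)
    ca, cb = annotation.loc[gene_a, "chromosome"], annotation.loc[gene_b, "chromosome"]
    if ca != cb:
        return EdgeCategory.TRANS
    if annotation.loc[gene_a, "cytoband"] == annotation.loc[gene_b, "cytoband"]:
        return EdgeCategory.INTRA_CYTOBAND
    return EdgeCategory.INTER_CYTOBAND_CIS


def classify_edges(edges, annotation: pd.DataFrame) -> pd.Series:
    """Vectorized per-edge categories (same order as the edge list)."""
    df = as_edge_frame(edges)
    _check_annotated(pd.concat([df["gene_a"], df["gene_b"]]), annotation)
    chrom = annotation["chromosome"]
    band = annotation["cytoband"]
    ca = chrom.loc[df["gene_a"]].to_numpy()
    cb = chrom.loc[df["gene_b"]].to_numpy()
    ba = band.loc[df["gene_a"]].to_numpy()
    bb = band.loc[df["gene_b"]].to_numpy()
    out = np.where(
        ca != cb,
        EdgeCategory.TRANS.value,
        np.where(
            ba == bb,
            EdgeCategory.INTRA_CYTOBAND.value,
            EdgeCategory.INTER_CYTOBAND_CIS.value,
        ),
    )
    return pd.Series(out, index=df.index, name="category")


def cis_trans_summary(edges, annotation: pd.DataFrame) -> dict:
    """Counts and fractions per edge category for one network."""
    df = as_edge_frame(edges)
    n = len(df)
    if n == 0:
        warnings.warn("empty edge set: all category counts are zero", stacklevel=2)
        return {
            "n_edges": 0,
            "cis": 0,
            "trans": 0,
            "intra_cytoband": 0,
            "inter_cytoband_cis": 0,
            "cis_fraction": 0.0,
            "trans_fraction": 0.0,
            "intra_cytoband_fraction": 0.0,
            "inter_cytoband_cis_fraction": 0.0,
        }
    cat = classify_edges(df, annotation)
    intra = int((cat == EdgeCategory.INTRA_CYTOBAND.value).sum())
    inter = int((cat == EdgeCategory.INTER_CYTOBAND_CIS.value).sum())
    trans = int((cat == EdgeCategory.TRANS.value).sum())
    cis = intra + inter
    return {
        "n_edges": n,
        "cis": cis,
        "trans": trans,
        "intra_cytoband": intra,
        "inter_cytoband_cis": inter,
        "cis_fraction": cis / n,
        "trans_fraction": trans / n,
        "intra_cytoband_fraction": intra / n,
        "inter_cytoband_cis_fraction": inter / n,
    }


def _region_key(annotation: pd.DataFrame, level: str) -> pd.Series:
    if level == "chromosome":
        return annotation["chromosome"].astype(str)
    if level == "cytoband":
        return annotation["chromosome"].astype(str) + ":" + annotation["cytoband"].astype(str)
    raise ValueError(f"level must be 'chromosome' or 'cytoband', got {level!r}")


def region_hotspots(
    edges,
    annotation: pd.DataFrame,
    level: str = "chromosome",
    universe: list[str] | None = None,
) -> pd.DataFrame:
    """Per-region intra-region edge frequency and proportion table.

    ``universe`` is the network's gene universe used for the pair-count
    denominator; by default every annotated gene. Regions with fewer than
    two universe genes get proportion 0 and ``degenerate`` = True. Sorted by
    frequency descending (region id breaks ties deterministically).
    """
    df = as_edge_frame(edges)
    if universe is None:
        universe = list(annotation.index)
    _check_annotated(universe, annotation)
    if len(df):
        _check_annotated(pd.concat([df["gene_a"], df["gene_b"]]), annotation)
    key = _region_key(annotation, level)
    n_genes = key.loc[universe].value_counts().sort_index()
    freq = pd.Series(0, index=n_genes.index, dtype=int)
    if len(df):
        ka = key.loc[df["gene_a"]].to_numpy()
        kb = key.loc[df["gene_b"]].to_numpy()
        intra = ka[ka == kb]
        counts = pd.Series(intra).value_counts()
        freq.loc[counts.index] = counts.astype(int)
    possible = n_genes * (n_genes - 1) // 2
    degenerate = possible == 0
    proportion = np.where(degenerate, 0.0, freq / possible.replace(0, 1))
    out = pd.DataFrame(
        {
            "region": n_genes.index,
            "frequency": freq.to_numpy(),
            "proportion": proportion,
            "n_genes": n_genes.to_numpy(),
            "degenerate": degenerate.to_numpy(),
        }
    )
    return (
        out.sort_values(["frequency", "region"], ascending=[False, True])
        .reset_index(drop=True)
    )


def per_sample_argmax_regions(
    sample_edges: dict[str, EdgeList] | list[EdgeList],
    annotation: pd.DataFrame,
    level: str = "chromosome",
    universe: list[str] | None = None,
) -> pd.DataFrame:
    """How many samples each region wins as that sample's top hotspot.

    For every sample's (top-k) edge set the region proportions are computed
    and every region attaining the maximum (only if positive) is credited;
    ties credit all tied regions, so totals can exceed the cohort size.
    Returns a frame (region, n_samples, n_tied_wins) sorted descending.
    """
    if isinstance(sample_edges, dict):
        items = list(sample_edges.items())
    else:
        items = [
            (e.meta.get("sample_id", str(i)), e) for i, e in enumerate(sample_edges)
        ]
    counts: dict[str, int] = {}
    tied: dict[str, int] = {}
    for sid, edges in items:
        table = region_hotspots(edges, annotation, level=level, universe=universe)
        top = table["proportion"].max()
        if not np.isfinite(top) or top <= 0:
            continue
        winners = table.loc[table["proportion"] == top, "region"].tolist()
        if len(winners) > 1:
            log.info("sample %s: argmax tie between %s", sid, winners)
        for region in winners:
            counts[region] = counts.get(region, 0) + 1
            if len(winners) > 1:
                tied[region] = tied.get(region, 0) + 1
    out = pd.DataFrame(
        {
            "region": list(counts.keys()),
            "n_samples": list(counts.values()),
            "n_tied_wins": [tied.get(r, 0) for r in counts],
        }
    )
    return (
        out.sort_values(["n_samples", "region"], ascending=[False, True])
        .reset_index(drop=True)
    )
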