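"""Recurrent high-degree genes across single-sample networks.

"High-degree" is operationalized as a sample's top-n genes by degree within
the largest connected component of its (top-k) network; recurrence is the
number of samples in which a gene makes that list. Recurrence totals can be
aggregated by (chromosome, cytoband) to localize hub activity.
"""

from __future__ import annotations

import pandas as pd

from .containers import as_edge_frame
from .netmetrics import largest_component
from .hotspots import _check_annotated

__all__ = ["high_degree_genes", "hub_recurrence", "hub_cytoband_distribution"]

TOP_N_DEFAULT = 10


def high_degree_genes(edges, top_n: int = TOP_N_DEFAULT) -> pd.DataFrame:
    """Top-n genes of the largest component ranked by degree.

    Ties break lexicographically by gene ID; if the component has fewer
    than ``top_n`` nodes, all are returned.
    """
    lcc = largest_component(edges).df
    degrees = (
        pd.concat([lcc["gene_a"], lcc["gene_b"]])
        .value_counts()
        .rename_axis("gene_id")
        .rename("degree")
        .reset_index()
        .sort_values(["degree", "gene_id"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return degrees.head(top_n)


def hub_recurrence(
    sample_edges: dict[str, object] | list, top_n: int = TOP_N_DEFAULT
) -> pd.DataFrame:
    """Per-gene count of samples in which it is a top-n high-degree gene."""
    nets = (
        list(sample_edges.values())
        if isinstance(sample_edges, dict)
        else list(sample_edges)
    )
    if len(nets) == 0:
        raise ValueError("need at least one network")
    counts: dict[str, int] = {}
    for net in nets:
        for gene in high_degree_genes(net, top_n=top_n)["gene_id"]:
            counts[gene] = counts.get(gene, 0) + 1
    out = pd.DataFrame(
        {"gene_id": list(counts.keys()), "recurrence": list(counts.values())}
    )
    return (
        out.sort_values(["recurrence", "gene_id"], ascending=[False, True])
        .reset_index(drop=True)
    )


def hub_cytoband_distribution(
    records: pd.DataFrame, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Recurrence totals aggregated by (chromosome, cytoband), descending."""
    if len(records) == 0:
        return pd.DataFrame(columns=["chromosome", "cytoband", "recurrence"])
    _check_annotated(records["gene_id"], annotation)
    joined = records.merge(
        annotation[["chromosome", "cytoband"]],
        left_on="gene_id",
        right_index=True,
    )
    out = (
        joined.groupby(["chromosome", "cytoband"], as_index=False)["recurrence"]
        .sum()
        .sort_values(
            ["recurrence", "chromosome", "cytoband"],
            ascending=[False, True, True],
        )
        .reset_index(drop=True)
    )
    return out
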