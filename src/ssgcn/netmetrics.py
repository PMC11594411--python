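"""Topology metrics on the largest connected component, group tests, Jaccard.

Metrics are computed on the binary adjacency of a (top-k) edge set's largest
connected component: average local clustering, modularity of a greedy
modularity-maximizing partition, mean closeness centrality, mean degree,
global efficiency and density. Group differences per metric are tested with
a two-sided Mann-Whitney U against a reference group, Benjamini-Hochberg
corrected across the metric x group family, with the ***/NS significance
convention at adjusted p < 0.001. Network coherence between an aggregated
network and its single-sample counterparts is the Jaccard index of the two
edge sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import EdgeList, as_edge_frame

__all__ = [
    "MetricsRecord",
    "largest_component",
    "compute_metrics",
    "compare_groups",
    "jaccard",
]

log = logging.getLogger(__name__)

METRIC_NAMES = (
    "avg_clustering",
    "modularity",
    "mean_closeness",
    "mean_degree",
    "global_efficiency",
    "density",
)


@dataclass
class MetricsRecord:
    """Largest-component topology metrics for one network."""

    network_id: str
    n_nodes_lcc: int
    n_edges_lcc: int
    avg_clustering: float
    modularity: float
    mean_closeness: float
    mean_degree: float
    global_efficiency: float
    density: float

    def as_dict(self) -> dict:
        return asdict(self)


def _graph(edges) -> nx.Graph:
    df = as_edge_frame(edges)
    g = nx.Graph()
    g.add_edges_from(zip(df["gene_a"], df["gene_b"]))
    return g


def largest_component(edges) -> EdgeList:
    """Edge sublist of the component with most nodes.

    Ties break by most edges, then by smallest lexicographic node.
    """
    df = as_edge_frame(edges)
    if len(df) == 0:
        raise ValueError("empty edge list has no components")
    g = _graph(df)
    comps = list(nx.connected_components(g))
    scored = sorted(
        comps, key=lambda c: (-len(c), -g.subgraph(c).number_of_edges(), min(c))
    )
    if len(comps) > 1 and len(scored[0]) == len(scored[1]):
        log.info("largest_component: tie on node count, tie rule applied")
    nodes = scored[0]
    keep = df["gene_a"].isin(nodes) & df["gene_b"].isin(nodes)
    prov = edges.provenance if isinstance(edges, EdgeList) else "aggregated"
    out = EdgeList(df.loc[keep].reset_index(drop=True), provenance=prov)
    if isinstance(edges, EdgeList):
        out.meta.update(edges.meta)
    return out


def compute_metrics(component, network_id: str = "", seed: int = 0) -> MetricsRecord:
    """Metrics of a connected component (>= 2 nodes).

    The community partition comes from greedy modularity maximization
    (deterministic; ``seed`` is accepted for the interface contract and
    recorded but the algorithm draws no random numbers).
    """
    g = _graph(component)
    if g.number_of_nodes() < 2:
        raise ValueError("metrics need a component with at least 2 nodes")
    if not nx.is_connected(g):
        raise ValueError("metrics are defined on a connected component")
    communities = nx.community.greedy_modularity_communities(g)
    degrees = [d for _, d in g.degree()]
    closeness = nx.closeness_centrality(g)
    return MetricsRecord(
        network_id=str(network_id),
        n_nodes_lcc=g.number_of_nodes(),
        n_edges_lcc=g.number_of_edges(),
        avg_clustering=float(nx.average_clustering(g)),
        modularity=float(nx.community.modularity(g, communities)),
        mean_closeness=float(np.mean(list(closeness.values()))),
        mean_degree=float(np.mean(degrees)),
        global_efficiency=float(nx.global_efficiency(g)),
        density=float(nx.density(g)),
    )


def metrics_table(records: list[MetricsRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in records])


def compare_groups(
    records_by_group: dict[str, list[MetricsRecord]],
    reference: str,
    metrics: tuple[str, ...] = METRIC_NAMES,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Mann-Whitney U of every non-reference group vs the reference per metric.

    Raw p-values are Benjamini-Hochberg adjusted across the whole
    metric x group family; labels are '***' below ``alpha`` (adjusted),
    otherwise 'NS'.
    """
    if reference not in records_by_group:
        raise ValueError(f"reference group {reference!r} missing")
    for name, recs in records_by_group.items():
        if len(recs) < 3:
            raise ValueError(f"group {name!r} needs at least 3 records")
    ref = metrics_table(records_by_group[reference])
    rows = []
    for name, recs in records_by_group.items():
        if name == reference:
            continue
        tab = metrics_table(recs)
        for metric in metrics:
            u, p = stats.mannwhitneyu(
                tab[metric], ref[metric], alternative="two-sided"
            )
            rows.append({"group": name, "metric": metric, "statistic": float(u), "p": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        out["label"] = np.where(out["p_adj"] < alpha, "***", "NS")
    return out


def jaccard(edge_set_a, edge_set_b) -> float:
    """Jaccard index of two edge sets (unordered gene pairs); 1 if both empty."""
    a = edge_set_a.pairs() if isinstance(edge_set_a, EdgeList) else {
        tuple(sorted(e)) for e in edge_set_a
    }
    b = edge_set_b.pairs() if isinstance(edge_set_b, EdgeList) else {
        tuple(sorted(e)) for e in edge_set_b
    }
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)
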