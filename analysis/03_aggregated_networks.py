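"""Infer the aggregated MI co-expression network per cohort (top 10,000 edges).

Reads scratch/preprocess/, writes scratch/aggregated/<cohort>.edges.tsv.
"""

from common import COHORTS, K_TOP, spath

from ssgcn import build_mi_matrix, candidate_pair_count, io, top_k_edges


def main() -> None:
    for cohort in COHORTS:
        norm = io.read_expression(
            spath("preprocess", f"{cohort}.normalized.tsv"), stage="normalized"
        )
        print(
            f"{cohort}: evaluating {candidate_pair_count(norm.n_genes):,} gene pairs "
            f"({norm.n_genes} genes)"
        )
        mim = build_mi_matrix(norm)
        edges = top_k_edges(mim, k=K_TOP)
        io.write_edge_list(edges, spath("aggregated", f"{cohort}.edges.tsv"))
        w = edges.df["weight"]
        print(
            f"{cohort}: kept top {len(edges):,} edges, "
            f"MI range [{w.min():.4f}, {w.max():.4f}] nats "
            f"(estimator: {mim.descriptor})"
        )


if __name__ == "__main__":
    main()
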