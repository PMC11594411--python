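"""Filter low-expression genes and TMM-normalize each cohort.

Reads scratch/data/expression_*.tsv; normalized matrices go to scratch/preprocess/,
removal reports to results/preprocess/.
"""

from common import COHORTS, DATA, path, spath

from ssgcn import filter_genes, io, normalize, tmm_factors


def main() -> None:
    for cohort in COHORTS:
        raw = io.read_expression(DATA / f"expression_{cohort}.tsv")
        filtered, report = filter_genes(raw)
        factors = tmm_factors(filtered)
        norm = normalize(filtered, factors)
        io.write_expression(norm, spath("preprocess", f"{cohort}.normalized.tsv"))
        report.to_csv(path("preprocess", f"{cohort}.removed.csv"), index=False)
        by_rule = report["rule"].value_counts().to_dict()
        print(
            f"{cohort}: kept {filtered.n_genes}/{raw.n_genes} genes "
            f"(removed by rule: {by_rule or 'none'}); "
            f"TMM factors in [{factors.factors.min():.3f}, {factors.factors.max():.3f}], "
            f"reference {factors.reference}"
        )


if __name__ == "__main__":
    main()
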