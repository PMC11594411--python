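"""Generate the synthetic study data: annotation plus two expression cohorts.

Writes scratch/data/{annotation.tsv, expression_normal.tsv, expression_cancer.tsv}.
"""

from common import COHORTS, DATA, study_config

from ssgcn import generate_annotation, generate_expression, io


def main() -> None:
    cfg = study_config()
    DATA.mkdir(parents=True, exist_ok=True)
    annotation = generate_annotation(cfg)
    io.write_annotation(annotation, DATA / "annotation.tsv")
    print(
        f"annotation: {len(annotation)} genes on "
        f"{annotation['chromosome'].nunique()} chromosomes, "
        f"{annotation.groupby(['chromosome', 'cytoband']).ngroups} cytobands"
    )
    for cohort, regime in COHORTS.items():
        expr = generate_expression(cfg, regime, annotation)
        io.write_expression(expr, DATA / f"expression_{cohort}.tsv")
        counts = expr.values.to_numpy()
        print(
            f"{cohort} ({regime}): {expr.n_genes} genes x {expr.n_samples} samples, "
            f"median count {int(counts.mean(axis=1).mean())}"
        )


if __name__ == "__main__":
    main()
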