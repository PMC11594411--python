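"""Recurrent high-degree genes across single-sample networks, by cytoband.

Per cohort: each sample's top-10 genes by degree in its largest component,
the recurrence of those genes across samples, and recurrence totals per
(chromosome, cytoband).
"""

import json

from common import COHORTS, DATA, path, spath

from ssgcn import hub_cytoband_distribution, hub_recurrence, io


def main() -> None:
    annotation = io.read_annotation(DATA / "annotation.tsv")
    for cohort in COHORTS:
        with open(spath("ssn", cohort, "manifest.json")) as fh:
            manifest = json.load(fh)
        nets = {
            sid: io.read_edge_list(spath("ssn", cohort, fname), provenance="single_sample")
            for sid, fname in manifest["samples"].items()
        }
        rec = hub_recurrence(nets, top_n=10)
        rec.to_csv(path("hubs", f"{cohort}.hub_recurrence.csv"), index=False)
        dist = hub_cytoband_distribution(rec, annotation)
        dist.to_csv(path("hubs", f"{cohort}.hub_cytobands.csv"), index=False)
        top_gene = rec.iloc[0]
        top_band = dist.iloc[0]
        print(
            f"{cohort}: top hub {top_gene['gene_id']} "
            f"(in the top-10 of {top_gene['recurrence']}/{len(nets)} samples); "
            f"hottest cytoband {top_band['chromosome']}:{top_band['cytoband']} "
            f"(summed recurrence {top_band['recurrence']})"
        )


if __name__ == "__main__":
    main()
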