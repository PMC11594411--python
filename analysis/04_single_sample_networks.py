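"""LIONESS single-sample networks: one top-10,000 edge list per sample.

Reads scratch/preprocess/, writes scratch/ssn/<cohort>/<sample>.edges.tsv
plus a manifest per cohort.
"""

import json

from common import COHORTS, K_TOP, spath

from ssgcn import all_sample_networks, io, mi_score, top_k_abs


def main() -> None:
    for cohort in COHORTS:
        norm = io.read_expression(
            spath("preprocess", f"{cohort}.normalized.tsv"), stage="normalized"
        )
        nets = all_sample_networks(norm, mi_score())
        samples = {}
        for net in nets:
            edges = top_k_abs(net, k=K_TOP)
            fname = f"{net.sample_id}.edges.tsv"
            io.write_edge_list(edges, spath("ssn", cohort, fname))
            samples[net.sample_id] = fname
        manifest = {
            "cohort": cohort,
            "n_cohort": norm.n_samples,
            "k": K_TOP,
            "samples": samples,
        }
        with open(spath("ssn", cohort, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        print(f"{cohort}: wrote {len(samples)} single-sample networks (N = {norm.n_samples})")


if __name__ == "__main__":
    main()
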