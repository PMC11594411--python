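"""Classify edges by genomic location and find co-expression hotspots.

CIS/TRANS summaries per network, chromosome and cytoband hotspot tables for
the aggregated networks, per-sample CIS fractions and per-sample argmax
region counts for the single-sample networks.
"""

import json

from common import COHORTS, DATA, path, spath

import pandas as pd
from ssgcn import (
    cis_trans_summary,
    io,
    per_sample_argmax_regions,
    region_hotspots,
)


def _load_ssn(cohort):
    with open(spath("ssn", cohort, "manifest.json")) as fh:
        manifest = json.load(fh)
    return {
        sid: io.read_edge_list(spath("ssn", cohort, fname), provenance="single_sample")
        for sid, fname in manifest["samples"].items()
    }


def main() -> None:
    annotation = io.read_annotation(DATA / "annotation.tsv")
    cis_fractions = {}
    for cohort in COHORTS:
        agg = io.read_edge_list(spath("aggregated", f"{cohort}.edges.tsv"))
        universe = io.read_expression(
            spath("preprocess", f"{cohort}.normalized.tsv"), stage="normalized"
        ).gene_ids
        summary = cis_trans_summary(agg, annotation)
        with open(path("hotspots", f"{cohort}.cis_trans.json"), "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        print(
            f"{cohort} aggregated: CIS {summary['cis_fraction']:.3f} "
            f"(intra-cytoband {summary['intra_cytoband_fraction']:.3f}), "
            f"TRANS {summary['trans_fraction']:.3f}"
        )
        for level in ("chromosome", "cytoband"):
            tab = region_hotspots(agg, annotation, level=level, universe=universe)
            tab.to_csv(path("hotspots", f"{cohort}.{level}_hotspots.csv"), index=False)
            top = tab.iloc[0]
            print(
                f"  top {level}: {top['region']} "
                f"(frequency {top['frequency']}, proportion {top['proportion']:.3f})"
            )
        ssn = _load_ssn(cohort)
        per_sample = []
        for sid, edges in ssn.items():
            s = cis_trans_summary(edges, annotation)
            s["sample_id"] = sid
            per_sample.append(s)
        per_sample = pd.DataFrame(per_sample)
        per_sample.to_csv(path("hotspots", f"{cohort}.per_sample_cis.csv"), index=False)
        cis_fractions[cohort] = per_sample["cis_fraction"].mean()
        for level in ("chromosome", "cytoband"):
            am = per_sample_argmax_regions(ssn, annotation, level=level, universe=universe)
            am.to_csv(path("hotspots", f"{cohort}.argmax_{level}.csv"), index=False)
            if len(am):
                print(
                    f"  per-sample argmax {level}: {am.iloc[0]['region']} "
                    f"wins {am.iloc[0]['n_samples']}/{len(ssn)} samples"
                )
    print(
        f"mean per-sample CIS fraction: cancer {cis_fractions['cancer']:.3f} "
        f"vs normal {cis_fractions['normal']:.3f} "
        f"({'cancer > normal' if cis_fractions['cancer'] > cis_fractions['normal'] else 'unexpected direction'})"
    )


if __name__ == "__main__":
    main()
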