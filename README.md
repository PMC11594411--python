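# ssgcn — single-sample gene co-expression network analysis

`ssgcn` studies how the genomic organization of gene co-expression differs
between phenotypes — in particular the shift from inter-chromosomal (TRANS)
co-expression toward intra-chromosomal (CIS) and intra-cytoband co-expression
that characterizes tumour cohorts — and asks whether that shift is visible in
*individual samples*, not just in cohort-level networks. It is aimed at
computational biologists working with RNA-seq count matrices, gene-level
genomic annotation and clinical follow-up.

## What it computes

1. **Preprocessing** — low-expression gene filtering (0.25-quantile of gene
   mean counts, all-zero genes, mean TMM-normalized count < 50) and TMM
   (trimmed mean of M-values) between-sample normalization.
2. **Aggregated networks** — mutual information *I(X;Y)* in nats for all
   C(G,2) gene pairs of a cohort (equal-frequency binning, plug-in estimator,
   optional Miller–Madow correction and DPI pruning), truncated to the top
   k = 10,000 edges.
3. **Single-sample networks (LIONESS)** — for sample *q* in a cohort of *N*
   samples, each edge score is

       e(q) = N · (e(α) − e(α−q)) + e(α−q)  =  N·e(α) − (N−1)·e(α−q)

   where e(α) uses all samples and e(α−q) leaves *q* out; each sample's
   network keeps the top 10,000 edges by |e(q)|.
4. **Genomic localization** — every edge is INTRA_CYTOBAND,
   INTER_CYTOBAND_CIS or TRANS; per-region hotspot tables report the
   intra-region edge frequency and the proportion frequency / C(n_genes, 2);
   per-sample argmax counts say how often each region is a sample's top
   hotspot.
5. **Topology** — largest-connected-component metrics (clustering,
   modularity, closeness, degree, global efficiency, density), Mann–Whitney
   group comparison with Benjamini–Hochberg correction, and the Jaccard index
   between aggregated and single-sample edge sets.
6. **Survival** — median split on per-sample CIS proportion, Kaplan–Meier
   curves, log-rank test, Cox proportional-hazards ratio, and a 5-year
   (1825-day) endpoint.
7. **Hubs** — recurrence of each sample's top-10 highest-degree genes across
   the cohort, localized to cytobands.

A synthetic-data module generates the two regimes this pipeline is designed
to distinguish: *normal-like* cohorts driven by global cross-chromosome
latent factors and *cancer-like* cohorts with high-correlation blocks planted
in specific cytobands, via a Gaussian copula onto negative-binomial counts,
plus exponential survival times with an optional group hazard effect.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic data
(300 genes on 5 chromosomes, 2 cytobands each; a 30-gene block at ρ = 0.8
planted in cytoband 1p11 of the cancer-like cohort; 50 samples per cohort):

```
cd analysis
python 01_simulate.py && python 02_preprocess.py && python 03_aggregated_networks.py
python 04_single_sample_networks.py && python 05_hotspots.py
python 06_network_metrics.py && python 07_survival.py && python 08_hubs.py
```

Selected output of `05_hotspots.py` and `08_hubs.py`:

```
normal aggregated: CIS 0.198 (intra-cytoband 0.098), TRANS 0.802
cancer aggregated: CIS 0.207 (intra-cytoband 0.108), TRANS 0.793
  top cytoband: 1:1p11 (frequency 253, proportion 1.000)
  per-sample argmax cytoband: 1:1p11 wins 48/50 samples
cancer: top hub G0003 (in the top-10 of 28/50 samples); hottest cytoband 1:1p11 (summed recurrence 139)
```

Reading: in the cancer-like cohort the planted cytoband 1p11 is a perfect
clique among the surviving genes (proportion 1.000 of its possible pairs),
it is the top hotspot of 48 of 50 individual networks, and its genes
dominate the recurrent hubs — while the cohort-level CIS fraction rises
only modestly (0.207 vs 0.198), which is exactly why the per-sample view is
informative. `07_survival.py` runs the CIS-proportion median split under a
null hazard (log HR = 0) and reports non-significant log-rank p-values, the
expected outcome.

Small summary tables land in `results/`; bulky intermediates (count
matrices, edge lists) go to `scratch/` and are regenerated on demand.

The same pipeline runs on real data from the shell: `ssgcn run-all --config
config.yaml` with paths to an expression TSV (genes × samples), a BED-like
annotation table (gene_id, chromosome, cytoband, start, end, gc, length) and
a clinical CSV (sample_id, time_days, event, subtype); see `ssgcn --help`
for the per-stage subcommands.

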