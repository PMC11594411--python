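# Methods

This note documents the models, estimators and design choices behind
`ssgcn`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what is computed, under which assumptions, with
which defaults, and what the synthetic benchmarks do and do not show.

## 1. Synthetic data generator

The generator exists so that every downstream stage can be exercised and
validated without any external download. It emulates two cohort regimes:

* **normal-like** — gene expression driven by `n_trans_factors` global
  latent factors. Each gene *g* receives a loading vector
  `w_g = trans_loading · s_g / √K` with independent random signs
  `s_g ∈ {−1, +1}^K`, and its latent value is `x_g = w_g·f + √(1 − λ²)·ε_g`
  (λ = `trans_loading`). Marginal variances are 1; pairwise correlations are
  `w_i·w_j ∈ [−λ², λ²]` and carry no relationship to genomic position, so
  the strongest co-expression is spread across chromosomes (TRANS-dominated).
* **cancer-like** — planted blocks: the first `n_genes` genes of a named
  cytoband share a factor, `x_g = √ρ·b + √(1−ρ)·ε_g`, giving exact pairwise
  correlation ρ inside the block and 0 elsewhere. Blocks may not overlap
  (overlap is rejected with the offending block named); the shared-factor
  construction makes the implied covariance positive semi-definite by
  construction rather than by a numerical check.

Latent Gaussians are mapped to counts by a Gaussian copula: gene means are
log-normal(`mean_log_mu`, `sd_log_mu`), all genes share the dispersion φ
(`nb_dispersion`; Var = μ + φμ²), and the count is the negative-binomial
quantile at Φ(x). The transform is monotone, so rank correlation — and hence
anything a rank-binning MI estimator sees — is preserved up to tie-induced
discretization. A consequence worth noting: the NB parameters (means,
dispersion) are essentially irrelevant to the network analysis; they matter
only for the preprocessing stage (filter thresholds, TMM) and for realism of
the count scale.

Survival: event times are exponential with hazard
`baseline_hazard · exp(log_hazard_ratio · 1[group = high])`. Censoring is
independent exponential with its rate chosen so that the probability of
being censored equals `censoring_rate` exactly (rate_c = rate_event ·
c/(1−c)); `censoring_rate = 0` disables censoring.

Defaults (`default_config()`): 300 genes = 5 chromosomes × 2 cytobands × 30
genes; one 30-gene block at ρ = 0.8 in cytoband 1p11; 5 trans factors at
loading 0.6; φ = 0.15, mean log-mean 6 (≈ 400 counts), SD 1; baseline hazard
1/1500 per day, log HR 0, censoring 0.3. These sizes keep a full LIONESS run
(100 samples × 44,850 pairs) in the tens of seconds on one CPU while leaving
the planted block large enough for stable recovery. Cytoband labels look
human-style ("1p11") but are opaque identifiers; nothing parses them, and a
cytoband is only identified together with its chromosome.

All randomness flows from one integer seed through named substreams
(CRC32 of the stage name mixed into the generator key), so outputs are
byte-identical across runs and insensitive to stage execution order.

**What the generator does not emulate:** batch effects, GC/length biases
(counts are generated without them, although a correction stage exists),
heavy-tailed library-size variation, correlated blocks spanning several
cytobands, competing risks, or informative censoring. Passing tests on this
generator therefore validate the machinery and its statistical calibration,
not performance on real tumour data.

## 2. Preprocessing

Filtering removes, in order, on the shrinking matrix: (1) genes whose mean
raw count is below the 0.25 linear-interpolation quantile of all gene mean
raw counts; (2) genes that are zero in every sample; (3) genes whose mean
TMM-normalized count is below 50. Each removal is reported per rule. A
quantile rule re-applied to its own output would remove another quartile, so
idempotence is provided by the matrix stage tag: a `filtered` matrix passes
through unchanged. If every gene would be removed, the error suggests
relaxing thresholds rather than returning an empty matrix.

TMM follows the canonical definition: reference = sample whose
upper-quartile count fraction is closest to the cohort mean; per-sample
log2 ratios M and abundances A over genes positive in both libraries;
double trim (30% of M, 5% of A, rank-based); weights = inverse asymptotic
binomial variance; factors rescaled to geometric mean 1. The implementation
is cross-checked in the test suite against edgeR's `calcNormFactors` (via
Rscript) to 1e-4 relative tolerance on a 500-gene fixture. Normalized
values are `count / (library_size × factor) × mean library size`, so a pure
depth change leaves a sample's normalized profile unchanged.

The optional GC/length stage residualizes log(count + 0.5) per sample
against GC fraction and then log length with lowess smoothers (frac 0.3),
re-centres on the sample mean and maps back to the count scale (−0.5,
clipped at 0). With constant covariates it is exactly the identity. It is
off by default: the synthetic counts carry no GC/length bias, and full
within-lane normalization is out of scope.

## 3. Mutual-information networks

The estimator is deliberately transparent so it can be validated against a
brute-force oracle: each profile is discretized into B equal-frequency bins
by rank (`B = max(2, ⌊n^⅓⌋)` by default; ties broken by original sample
index; a constant profile collapses to one bin with a warning and MI 0),
and MI is the plug-in estimate from the B×B joint histogram, in nats,
floored at 0. The optional Miller–Madow correction adds
`(m_xy − m_x − m_y + 1)/(2n)` (occupied-cell counts); it is off by default
because ranking — the only thing the pipeline consumes — is nearly invariant
to it. The all-pairs computation one-hot encodes bin codes and obtains all
joint histograms as a single matrix product, which makes the result
trivially independent of work partitioning; binning is done on columns
sorted by sample ID so the matrix is invariant to column order.

DPI pruning (off by default) removes edge (i,j) when some third gene k has
`min(MI(i,k), MI(j,k))·(1 − tolerance) > MI(i,j)` with all three MIs
positive, deciding all removals on the input matrix and applying them
together. Truncation keeps the k = 10,000 strongest edges; ties at the
cutoff break lexicographically by gene pair so every downstream table is
reproducible. For single-sample networks the ranking uses |e(q)| and the
signed weight is preserved in outputs.

## 4. LIONESS

`e(q) = N·e(α) − (N−1)·e(α−q)` with e(α) computed once per cohort and each
leave-one-out score recomputed from scratch (O(N·G²) for histogram MI; no
incremental shortcut exists for a rank-binned estimator because removing a
sample re-bins every gene). The score function is pluggable: MI (default),
Pearson, and a linear per-sample-mean stub whose exact algebra
(mean_q e(q) = e(α)) is used as an oracle in the tests.

A property of LIONESS-MI worth knowing when interpreting hotspot recovery:
for a sample whose latent block factor happens to sit near zero, leaving it
out *raises* the cohort MI of block edges, so its own network legitimately
de-emphasizes the block. In the default planted-block conditions (ρ = 0.8,
30-gene block, 100 samples, top-10,000 of 44,850 pairs) the planted cytoband
is the per-sample argmax hotspot in roughly nine of ten single-sample
networks, with the remainder being exactly these low-factor samples — a
feature of single-sample inference, not an estimator failure.

## 5. Hotspots and localization

Edges partition into INTRA_CYTOBAND, INTER_CYTOBAND_CIS and TRANS;
CIS = the first two. The hotspot proportion divides the intra-region edge
frequency by C(n_region_genes, 2) over the network's gene universe (the
genes of the cohort matrix the network was built from). This is the only
normalization bounded in [0,1] at the edge level, equals 1 exactly when the
region's universe genes form a clique, and regions with fewer than two
universe genes are flagged degenerate with proportion 0. Per-sample argmax
counting credits every region attaining the (positive) maximum proportion;
ties credit all tied regions, so totals can exceed the cohort size (tie
counts are reported alongside). Genes are assigned to exactly one cytoband
by the annotation; a gene spanning a boundary belongs to the band of its
start coordinate.

## 6. Topology metrics

Metrics are computed on the binary adjacency of the largest connected
component (ties: most nodes, then most edges, then smallest lexicographic
node): average local clustering (nodes of degree < 2 contribute 0),
modularity of the greedy modularity-maximizing partition (the networkx
implementation is deterministic; a seed argument is accepted and recorded
for the interface contract), mean closeness centrality, mean degree, global
efficiency (mean over ordered pairs of inverse shortest-path length) and
density 2E/(V(V−1)). "Centrality" is read as closeness centrality; no
separate betweenness metric is computed. Group differences use a two-sided
Mann–Whitney U of each group against the reference, BH-adjusted across the
metric × group family, labelled `***` below adjusted p = 0.001 and `NS`
otherwise — a rank test because the metric distributions across samples are
bounded and skewed. Edge weights are ignored, consistent with the top-k
truncation framing. The Jaccard index |A∩B|/|A∪B| compares edge sets as
unordered pairs; two empty sets are defined as identical (1).

## 7. Survival

Groups are assigned per subtype: "high" strictly above the within-subtype
median CIS proportion, ties to "low" (an all-equal subtype becomes all-low
with a warning). Kaplan–Meier estimation, the two-group log-rank test and
the Cox proportional-hazards fit are delegated to lifelines behind the
module surface; Cox uses Efron tie handling (the lifelines default). A
subtype where neither group has any event returns log-rank p = 1 with a
warning instead of an error; a Cox fit without events is an error. The
5-year endpoint truncates administratively at 1825 days: strictly larger
times become censored at 1825, the boundary itself is untouched, and
truncation can only decrease the event count. Analyses run per subtype and
are never pooled.

Calibration at the defaults, recomputed by `scripts/acceptance.py` and the
test suite: the log-rank type-I error over 1000 null replicates (n = 100,
no censoring) falls inside [0.036, 0.064] at α = 0.05, and the mean Cox
log-HR over replicates at n = 500 with 20% censoring recovers ln 2 within
±0.1.

## 8. Numerical and I/O conventions

Floats are written with 17 significant digits, so write→read round trips
are exact to < 1e-12; tables are sorted with explicit deterministic
tie-breaks before writing; coordinates are 1-based inclusive; chromosome
names are normalized by stripping a leading `chr`. The pipeline manifest
records the config hash, seed and per-stage outputs, and every stage can be
resumed from the previous stage's files. Problem sizes in the bundled
analysis (300 genes, 2 × 50 samples, k = 10,000) were chosen so the full
study runs in a few minutes on a single CPU; the tests use smaller cohorts
with the same structure.

## 9. Known limitations

* The MI estimator is a fixed-bin plug-in; adaptive-partitioning or kernel
  estimators are out of scope, and MI values carry plug-in bias
  ≈ (B−1)²/2n that cancels in ranking but not in absolute terms.
* Leave-one-out re-binning makes LIONESS-MI scores noisier than LIONESS on
  smooth statistics (e.g., Pearson); at desk-scale gene counts the top-k
  cutoff admits an appreciable noise floor (k/C(G,2) ≈ 22% here vs ≈ 0.08%
  at 5000 genes), which compresses the CIS-fraction contrast between
  regimes relative to larger universes.
* DPI application order relative to truncation is configurable because the
  canonical choice is ambiguous; the default ranks raw MI and truncates.
* The survival module fits a single binary covariate; no multivariable
  adjustment, stratified baselines or competing risks.
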