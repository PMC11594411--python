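"""Synthetic cohorts with planted genomic co-expression structure.

The generator emulates the two data regimes the downstream analysis is built
to distinguish:

* ``normal_like`` -- expression driven by a handful of global latent factors
  whose gene loadings ignore genomic position, so strong co-expression is
  spread across chromosomes (TRANS-dominated, as in healthy tissue).
* ``cancer_like`` -- expression with high-correlation blocks confined to
  specific cytobands (CIS/intra-cytoband hotspots, as in tumour cohorts).

Latent Gaussian vectors with the chosen correlation structure are pushed
through a Gaussian copula onto negative-binomial margins, giving
over-dispersed RNA-seq-like counts while preserving rank correlation so that
a mutual-information estimator can recover the planted structure.
Survival times are exponential with an optional proportional-hazards effect
for a "high" group, plus independent exponential censoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .containers import ExpressionMatrix

__all__ = [
    "PlantedBlock",
    "SurvivalParams",
    "SimulationConfig",
    "generate_annotation",
    "generate_expression",
    "generate_clinical",
    "default_config",
]


@dataclass(frozen=True)
class PlantedBlock:
    """A high-correlation gene block confined to one cytoband.

    ``chromosome``/``cytoband`` name the region (cytoband labels are only
    unique within their chromosome), ``n_genes`` genes of that cytoband are
    wired to a shared latent factor with pairwise correlation ``rho``.
    """

    chromosome: str
    cytoband: str
    n_genes: int
    rho: float


@dataclass(frozen=True)
class SurvivalParams:
    """Exponential survival model: hazard per day, group log-HR, censoring.

    ``censoring_rate`` is the probability that a subject is censored before
    its event; censoring times are exponential with the rate chosen to give
    exactly that probability.
    """

    baseline_hazard: float = 1.0 / 1500.0
    log_hazard_ratio: float = 0.0
    censoring_rate: float = 0.3


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int
    chromosome_sizes: tuple[int, ...]
    cytobands_per_chromosome: int
    n_samples: int
    planted_blocks: tuple[PlantedBlock, ...] = ()
    n_trans_factors: int = 0
    trans_loading: float = 0.0
    nb_dispersion: float = 0.15
    mean_log_mu: float = 6.0
    sd_log_mu: float = 1.0
    seed: int = 0
    survival: SurvivalParams = field(default_factory=SurvivalParams)

    def __post_init__(self):
        object.__setattr__(self, "chromosome_sizes", tuple(self.chromosome_sizes))
        object.__setattr__(self, "planted_blocks", tuple(self.planted_blocks))
        if self.n_genes <= 0 or self.n_samples <= 0:
            raise ValueError("n_genes and n_samples must be positive")
        if sum(self.chromosome_sizes) != self.n_genes:
            raise ValueError(
                f"chromosome_sizes sum to {sum(self.chromosome_sizes)}, "
                f"expected n_genes = {self.n_genes}"
            )
        if any(s <= 0 for s in self.chromosome_sizes):
            raise ValueError("chromosome sizes must be positive")
        if self.cytobands_per_chromosome <= 0:
            raise ValueError("cytobands_per_chromosome must be positive")
        if not 0.0 <= self.trans_loading < 1.0:
            raise ValueError("trans_loading must be in [0, 1)")
        if self.n_trans_factors < 0:
            raise ValueError("n_trans_factors must be non-negative")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.sd_log_mu <= 0:
            raise ValueError("sd_log_mu must be positive")
        for b in self.planted_blocks:
            if not 0.0 <= b.rho < 1.0:
                raise ValueError(
                    f"planted block {b.chromosome}:{b.cytoband}: rho must be in [0, 1)"
                )
            if b.n_genes < 2:
                raise ValueError(
                    f"planted block {b.chromosome}:{b.cytoband}: needs >= 2 genes"
                )
        if not 0.0 <= self.survival.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in [0, 1)")


def default_config(seed: int = 0, n_samples: int = 100) -> SimulationConfig:
    """Reference study conditions used throughout the analysis scripts.

    300 genes on 5 chromosomes (2 cytobands of 30 genes each), one planted
    30-gene block at rho = 0.8 filling the first cytoband of chromosome 1
    (cancer-like regime), and 5 global trans factors at loading 0.6
    (normal-like regime).
    """
    return SimulationConfig(
        n_genes=300,
        chromosome_sizes=(60,) * 5,
        cytobands_per_chromosome=2,
        n_samples=n_samples,
        planted_blocks=(PlantedBlock("1", "1p11", 30, 0.8),),
        n_trans_factors=5,
        trans_loading=0.6,
        nb_dispersion=0.15,
        mean_log_mu=6.0,
        sd_log_mu=1.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# annotation


def _cytoband_labels(chrom: str, k: int) -> list[str]:
    # Human-style labels ("1p11", "1q21"): first half of the bands on the p
    # arm, rest on q. Labels are arbitrary identifiers; nothing downstream
    # parses them for position.
    labels = []
    n_p = (k + 1) // 2
    for j in range(k):
        if j < n_p:
            labels.append(f"{chrom}p{j + 1}1")
        else:
            labels.append(f"{chrom}q{j - n_p + 1}1")
    return labels


def generate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Gene annotation table: chromosome, cytoband, coordinates, GC, length.

    Genes are assigned to chromosomes in config order; within a chromosome
    they are split as evenly as possible among its cytobands and laid out on
    non-overlapping, increasing 1-based inclusive intervals.
    """
    rng = substream(config.seed, "annotation")
    width = max(4, len(str(config.n_genes)))
    rows = []
    gene_idx = 0
    for c, size in enumerate(config.chromosome_sizes, start=1):
        chrom = str(c)
        k = config.cytobands_per_chromosome
        bands = _cytoband_labels(chrom, k)
        base, extra = divmod(size, k)
        counts = [base + (1 if j < extra else 0) for j in range(k)]
        pos = 1
        for band, n_band in zip(bands, counts):
            for _ in range(n_band):
                length = int(rng.integers(500, 20001))
                gap = int(rng.integers(100, 5001))
                start = pos
                end = start + length - 1
                pos = end + gap
                rows.append(
                    {
                        "gene_id": f"G{gene_idx:0{width}d}",
                        "chromosome": chrom,
                        "cytoband": band,
                        "start": start,
                        "end": end,
                        "gc_fraction": round(float(rng.uniform(0.3, 0.7)), 4),
                        "length": length,
                    }
                )
                gene_idx += 1
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# expression


def _block_gene_indices(
    config: SimulationConfig, annotation: pd.DataFrame
) -> list[np.ndarray]:
    """Row indices of each planted block's genes; validates block geometry."""
    taken = np.zeros(len(annotation), dtype=bool)
    out = []
    for b in config.planted_blocks:
        mask = (annotation["chromosome"] == b.chromosome) & (
            annotation["cytoband"] == b.cytoband
        )
        idx = np.flatnonzero(mask.to_numpy())
        if len(idx) == 0:
            raise ValueError(
                f"planted block {b.chromosome}:{b.cytoband}: cytoband not found"
            )
        if b.n_genes > len(idx):
            raise ValueError(
                f"planted block {b.chromosome}:{b.cytoband}: requests "
                f"{b.n_genes} genes but the cytoband has {len(idx)}"
            )
        idx = idx[: b.n_genes]
        if taken[idx].any():
            raise ValueError(
                f"planted block {b.chromosome}:{b.cytoband}: overlaps another "
                "block (implied covariance would not be valid)"
            )
        taken[idx] = True
        out.append(idx)
    return out


def latent_expression(
    config: SimulationConfig, regime: str, annotation: pd.DataFrame | None = None
) -> np.ndarray:
    """Latent Gaussian genes x samples matrix for the given regime.

    ``cancer_like`` activates the planted cytoband blocks; ``normal_like``
    activates the global trans factors. Marginal variances are 1 either way,
    so the implied covariance is a correlation matrix and positive
    semi-definite by construction (shared-factor representation).
    """
    if regime not in ("normal_like", "cancer_like"):
        raise ValueError(f"unknown regime {regime!r}")
    if annotation is None:
        annotation = generate_annotation(config)
    rng = substream(config.seed, f"latent:{regime}")
    g, n = config.n_genes, config.n_samples
    z = rng.standard_normal((g, n))
    if regime == "cancer_like":
        x = z.copy()
        for b, idx in zip(config.planted_blocks, _block_gene_indices(config, annotation)):
            shared = rng.standard_normal(n)
            x[idx] = np.sqrt(b.rho) * shared + np.sqrt(1.0 - b.rho) * z[idx]
        return x
    k, tl = config.n_trans_factors, config.trans_loading
    if k == 0 or tl == 0.0:
        return z
    factors = rng.standard_normal((k, n))
    signs = rng.choice([-1.0, 1.0], size=(g, k))
    loadings = tl * signs / np.sqrt(k)  # each gene: ||w|| = trans_loading
    return loadings @ factors + np.sqrt(1.0 - tl**2) * z


def generate_expression(
    config: SimulationConfig,
    regime: str,
    annotation: pd.DataFrame | None = None,
    sample_prefix: str | None = None,
) -> ExpressionMatrix:
    """Negative-binomial count matrix via a Gaussian copula on the latents.

    Gene means are log-normal(mean_log_mu, sd_log_mu); all genes share the
    dispersion ``nb_dispersion`` (variance = mu + dispersion * mu^2). The
    copula uses the NB quantile function at the Gaussian CDF value, which
    preserves rank correlation.
    """
    if annotation is None:
        annotation = generate_annotation(config)
    x = latent_expression(config, regime, annotation)
    rng = substream(config.seed, f"margins:{regime}")
    mu = np.exp(rng.normal(config.mean_log_mu, config.sd_log_mu, config.n_genes))
    r = 1.0 / config.nb_dispersion
    p = r / (r + mu)
    u = stats.norm.cdf(x)
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    counts = stats.nbinom.ppf(u, r, p[:, None]).astype(np.int64)
    prefix = sample_prefix if sample_prefix is not None else regime[0].upper()
    samples = [f"{prefix}S{j:04d}" for j in range(config.n_samples)]
    df = pd.DataFrame(counts, index=annotation.index, columns=samples)
    return ExpressionMatrix(df, stage="raw")


# ---------------------------------------------------------------------------
# clinical


def generate_clinical(
    config: SimulationConfig, group_labels: pd.Series | dict
) -> pd.DataFrame:
    """Survival table for the labelled samples.

    Event times are exponential with hazard
    ``baseline_hazard * exp(log_hazard_ratio * 1[high])``; censoring times
    are independent exponentials calibrated so the censoring probability is
    ``censoring_rate``. Observed time = min(event, censoring).
    """
    labels = pd.Series(dict(group_labels) if not isinstance(group_labels, pd.Series) else group_labels)
    if len(labels) == 0:
        raise ValueError("empty cohort: no samples to generate clinical data for")
    bad = sorted(set(labels.unique()) - {"high", "low"})
    if bad:
        raise ValueError(f"group labels must be 'high' or 'low'; got {bad}")
    sp = config.survival
    rng = substream(config.seed, "clinical")
    hazard = sp.baseline_hazard * np.exp(
        sp.log_hazard_ratio * (labels.to_numpy() == "high")
    )
    t_event = rng.exponential(1.0 / hazard)
    if sp.censoring_rate > 0:
        cens_hazard = hazard * sp.censoring_rate / (1.0 - sp.censoring_rate)
        t_cens = rng.exponential(1.0 / cens_hazard)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time = t_event
        event = np.ones(len(labels), dtype=int)
    return pd.DataFrame(
        {
            "sample_id": labels.index.astype(str),
            "time_days": time,
            "event": event,
            "group": labels.to_numpy(),
        }
    ).reset_index(drop=True)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different seed (replicate runs)."""
    return replace(config, seed=seed)
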