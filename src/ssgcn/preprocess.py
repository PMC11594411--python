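"""Gene filtering and TMM between-sample normalization for count matrices.

Filtering removes, in order on the shrinking matrix: (1) genes whose mean
raw count falls below the 25th percentile of gene mean raw counts, (2) genes
with zero counts in every sample, (3) genes whose mean TMM-normalized count
is below 50.  TMM (trimmed mean of M-values) follows the canonical
definition: per-sample scale factor from a doubly trimmed (30% on M, 5% on A),
precision-weighted mean of per-gene log2 ratios against a reference sample,
rescaled to geometric mean 1.

An optional within-sample GC/length correction (loess-style residualization)
is provided but off by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import ExpressionMatrix

__all__ = [
    "NormalizationFactors",
    "tmm_factors",
    "normalize",
    "filter_genes",
    "gc_length_correct",
    "MEAN_NORMALIZED_COUNT_MIN",
    "LOW_EXPRESSION_QUANTILE",
]

log = logging.getLogger(__name__)

LOW_EXPRESSION_QUANTILE = 0.25
MEAN_NORMALIZED_COUNT_MIN = 50.0


@dataclass
class NormalizationFactors:
    """Per-sample TMM scale factors (geometric mean 1) and the reference."""

    factors: pd.Series
    reference: str

    def __post_init__(self):
        if (self.factors <= 0).any():
            raise ValueError("all normalization factors must be positive")


def _counts_frame(counts) -> pd.DataFrame:
    return counts.values if isinstance(counts, ExpressionMatrix) else counts


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    log_ratio_trim: float = 0.30,
    abs_expr_trim: float = 0.05,
) -> float:
    """TMM factor of one sample against the reference (log2 scale -> linear)."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        return 1.0
    po, pr = obs / lib_obs, ref / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    w = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    finite = np.isfinite(m) & np.isfinite(a) & (w > 0)
    m, a, w = m[finite], a[finite], w[finite]
    n = m.size
    if n == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    # double trim by rank, as in the canonical implementation
    lo_m = np.floor(n * log_ratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_expr_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 1.0
    f = np.nansum(m[keep2] / w[keep2]) / np.nansum(1.0 / w[keep2])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(counts) -> NormalizationFactors:
    """TMM scale factors for every sample of a count matrix.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean upper-quartile fraction across samples.
    """
    df = _counts_frame(counts)
    if df.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = df.sum(axis=0).astype(float)
    zero_lib = lib.index[lib == 0].tolist()
    if zero_lib:
        raise ValueError(f"samples with all-zero counts: {zero_lib}")
    uq = (df / lib).quantile(0.75, axis=0)
    reference = (uq - uq.mean()).abs().idxmin()
    ref_col = df[reference].to_numpy()
    raw = {}
    for s in df.columns:
        if s == reference:
            raw[s] = 1.0
        else:
            raw[s] = _tmm_pair(df[s].to_numpy(), ref_col, lib[s], lib[reference])
    factors = pd.Series(raw, name="tmm_factor").loc[df.columns]
    factors = factors / np.exp(np.log(factors).mean())  # geometric mean 1
    return NormalizationFactors(factors=factors, reference=str(reference))


def normalize(counts, factors: NormalizationFactors | None = None) -> ExpressionMatrix:
    """Scale counts to a common effective library size.

    value(g, s) = count(g, s) / (library_size(s) * factor(s)) * mean library size.
    """
    df = _counts_frame(counts)
    if factors is None:
        factors = tmm_factors(df)
    lib = df.sum(axis=0).astype(float)
    eff = lib * factors.factors.loc[df.columns]
    out = df / eff * lib.mean()
    return ExpressionMatrix(out, stage="normalized")


def filter_genes(raw) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Apply the three low-expression filters; return matrix + removal report.

    Rules run sequentially on the shrinking matrix:

    1. mean raw count below the 0.25 quantile of gene mean raw counts;
    2. zero counts in every sample;
    3. mean TMM-normalized count below 50.

    A matrix already tagged ``filtered`` passes through unchanged, so the
    operation is idempotent.
    """
    if isinstance(raw, ExpressionMatrix):
        if raw.stage == "filtered":
            log.info("filter_genes: input already filtered; no-op")
            return raw, pd.DataFrame(columns=["gene_id", "rule"])
        if raw.stage == "normalized":
            raise ValueError("filter_genes expects raw counts, got a normalized matrix")
        df = raw.values
    else:
        df = raw
    removed: list[tuple[str, str]] = []

    means = df.mean(axis=1)
    threshold = float(np.quantile(means.to_numpy(), LOW_EXPRESSION_QUANTILE))
    drop1 = means.index[means < threshold]
    removed += [(g, "low_quantile") for g in drop1]
    df = df.drop(index=drop1)

    drop2 = df.index[(df == 0).all(axis=1)]
    removed += [(g, "all_zero") for g in drop2]
    df = df.drop(index=drop2)

    if df.shape[0] == 0:
        raise ValueError(
            "no genes left after quantile/zero filters; relax the thresholds"
        )
    norm = normalize(df).values
    drop3 = norm.index[norm.mean(axis=1) < MEAN_NORMALIZED_COUNT_MIN]
    removed += [(g, "mean_tmm_below_50") for g in drop3]
    df = df.drop(index=drop3)

    if df.shape[0] == 0:
        raise ValueError("no genes left after filtering; relax the thresholds")
    report = pd.DataFrame(removed, columns=["gene_id", "rule"])
    return ExpressionMatrix(df, stage="filtered"), report


def _residualize(y: np.ndarray, x: np.ndarray, frac: float = 0.3) -> np.ndarray:
    """Residuals of a lowess fit of y on x (mean fit if x is constant)."""
    if np.ptp(x) == 0:
        return y - y.mean()
    fitted = lowess(y, x, frac=frac, return_sorted=False)
    return y - fitted


def gc_length_correct(
    counts, annotation: pd.DataFrame, enabled: bool = True
) -> ExpressionMatrix:
    """Optional within-sample correction for GC content and gene length.

    Per sample, log(count + 0.5) is residualized against GC fraction and
    then against log length with loess-style smoothers; residuals are
    re-centred on the sample mean and mapped back to the count scale.
    """
    df = _counts_frame(counts)
    if not enabled:
        log.info("gc_length_correct: skipped")
        return ExpressionMatrix(df, stage="normalized")
    missing = sorted(set(df.index) - set(annotation.index))
    if missing:
        raise ValueError(f"genes missing from annotation: {missing}")
    ann = annotation.loc[df.index]
    gc = ann["gc_fraction"].to_numpy(dtype=float)
    loglen = np.log(ann["length"].to_numpy(dtype=float))
    out = np.empty(df.shape)
    for j, s in enumerate(df.columns):
        y = np.log(df[s].to_numpy(dtype=float) + 0.5)
        center = y.mean()
        resid = _residualize(y, gc)
        resid = _residualize(resid, loglen)
        out[:, j] = np.maximum(np.exp(resid + center) - 0.5, 0.0)
    return ExpressionMatrix(
        pd.DataFrame(out, index=df.index, columns=df.columns), stage="normalized"
    )
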