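"""Survival stratification by single-sample CIS proportion.

Samples are split at the within-subtype median of their CIS proportion
(strictly above the median -> "high", ties go to "low"); groups are compared
with Kaplan-Meier curves, the two-group log-rank test and a univariate Cox
proportional-hazards model (Efron tie handling). A 5-year endpoint is
available by administrative truncation at 1825 days.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "FIVE_YEARS_DAYS",
    "split_by_cis",
    "km_estimate",
    "logrank_test",
    "cox_hazard_ratio",
    "truncate_5year",
]

FIVE_YEARS_DAYS = 1825.0


def _validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "time_days", "event"}
    missing = required - set(clinical.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    if (clinical["time_days"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not clinical["event"].isin([0, 1]).all():
        raise ValueError("event flags must be 0 or 1")
    return clinical


def split_by_cis(cis_proportions: pd.Series, clinical: pd.DataFrame) -> pd.DataFrame:
    """Assign high/low groups at the per-subtype median CIS proportion.

    ``cis_proportions`` maps sample_id -> CIS fraction of that sample's
    single-sample network. Group is "high" when the proportion is strictly
    above the median of its subtype (column ``subtype`` if present,
    otherwise one pooled stratum); ties go to "low".
    """
    clinical = _validate_clinical(clinical).copy()
    missing = sorted(set(clinical["sample_id"]) - set(cis_proportions.index))
    if missing:
        raise ValueError(f"samples without a CIS proportion: {missing}")
    clinical["cis_proportion"] = cis_proportions.loc[clinical["sample_id"]].to_numpy()
    strata = (
        clinical["subtype"]
        if "subtype" in clinical.columns
        else pd.Series("all", index=clinical.index)
    )
    groups = np.empty(len(clinical), dtype=object)
    for subtype in strata.unique():
        mask = (strata == subtype).to_numpy()
        values = clinical.loc[mask, "cis_proportion"]
        med = float(values.median())
        high = values > med
        if not high.any():
            warnings.warn(
                f"subtype {subtype!r}: no sample strictly above the median CIS "
                "proportion; all assigned to 'low'",
                stacklevel=2,
            )
        groups[mask] = np.where(high, "high", "low")
    clinical["group"] = groups
    return clinical


def km_estimate(
    times, events, timeline=None, label: str = "KM"
) -> tuple[pd.DataFrame, KaplanMeierFitter]:
    """Product-limit survival curve with Greenwood-based CIs and risk counts."""
    kmf = KaplanMeierFitter(label=label)
    kmf.fit(times, event_observed=events, timeline=timeline)
    ci = kmf.confidence_interval_survival_function_
    table = pd.DataFrame(
        {
            "time": kmf.survival_function_.index,
            "survival": kmf.survival_function_[label].to_numpy(),
            "ci_lower": ci.iloc[:, 0].to_numpy(),
            "ci_upper": ci.iloc[:, 1].to_numpy(),
            "at_risk": [
                int(kmf.event_table["at_risk"].loc[:t].iloc[-1]) if t > 0 else len(np.asarray(times))
                for t in kmf.survival_function_.index
            ],
        }
    ).reset_index(drop=True)
    return table, kmf


def logrank_test(
    times_a, events_a, times_b, events_b
) -> tuple[float, float]:
    """Two-group log-rank test (1 df); returns (chi-square, p)."""
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    events_a, events_b = np.asarray(events_a, int), np.asarray(events_b, int)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if events_a.sum() == 0 and events_b.sum() == 0:
        warnings.warn("no events in either group; log-rank p set to 1", stacklevel=2)
        return 0.0, 1.0
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def cox_hazard_ratio(clinical: pd.DataFrame) -> dict:
    """Univariate Cox PH fit of the high-vs-low group indicator (Efron ties).

    Returns hazard ratio for "high" vs "low" with 95% CI and Wald p-value.
    """
    clinical = _validate_clinical(clinical)
    if "group" not in clinical.columns:
        raise ValueError("clinical table needs a 'group' column")
    if int(clinical["event"].sum()) == 0:
        raise ValueError("no events observed; Cox model cannot be fit")
    for grp in ("high", "low"):
        sub = clinical[clinical["group"] == grp]
        if len(sub) and sub["event"].sum() == 0:
            warnings.warn(f"group {grp!r} has no events", stacklevel=2)
    data = pd.DataFrame(
        {
            "time_days": clinical["time_days"].to_numpy(dtype=float),
            "event": clinical["event"].to_numpy(dtype=int),
            "high": (clinical["group"] == "high").astype(int).to_numpy(),
        }
    )
    if data["high"].nunique() < 2:
        raise ValueError("both groups must be represented to estimate a hazard ratio")
    cph = CoxPHFitter()
    cph.fit(data, duration_col="time_days", event_col="event")
    summary = cph.summary.loc["high"]
    return {
        "log_hr": float(summary["coef"]),
        "hr": float(summary["exp(coef)"]),
        "ci_lower": float(np.exp(summary["coef lower 95%"])),
        "ci_upper": float(np.exp(summary["coef upper 95%"])),
        "p": float(summary["p"]),
        "n": int(len(data)),
        "n_events": int(data["event"].sum()),
    }


def truncate_5year(clinical: pd.DataFrame, cutoff: float = FIVE_YEARS_DAYS) -> pd.DataFrame:
    """Administrative truncation at the 5-year endpoint (1825 days).

    Times strictly beyond the cutoff become censored at the cutoff; a time
    exactly at the cutoff is unchanged.
    """
    out = _validate_clinical(clinical).copy()
    over = out["time_days"] > cutoff
    out.loc[over, "time_days"] = cutoff
    out.loc[over, "event"] = 0
    return out
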