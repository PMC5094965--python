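"""Median-dichotomized survival association and cohort summaries.

Biomarker values (abnormality score or TEff index) are split at the cohort
median into low/high groups, compared by Kaplan-Meier curves and the
two-sample log-rank test. The CRPC endpoint is overall survival from first
collection after ADT failure; the HSPC endpoint is progression to
castration resistance — the endpoint is a configuration choice, not
hardcoded.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import InvalidInputError


@dataclass
class KMResult:
    groups: pd.Series                 # per-patient "low"/"high"
    curves: dict[str, pd.DataFrame]   # per-group (time, at_risk, survival)
    logrank_stat: float | None
    p_value: float | None
    cutoff: float


def dichotomize_by_median(values: pd.Series) -> tuple[pd.Series, float]:
    """Split patients at the median: value <= median -> "low", else "high".

    The median is the midpoint of the two central order statistics for
    even n. All-identical values cannot be dichotomized and raise.
    """
    values = pd.Series(values).astype(float)
    if len(values) < 4:
        raise InvalidInputError("need >= 4 patients to dichotomize")
    if values.nunique() == 1:
        raise InvalidInputError("all values identical; dichotomy degenerate")
    cutoff = float(values.median())
    groups = pd.Series(np.where(values <= cutoff, "low", "high"),
                       index=values.index)
    return groups, cutoff


def km_logrank(times, events, groups) -> KMResult:
    """Kaplan-Meier curves per group plus the two-group log-rank test.

    Uses the product-limit estimator; the log-rank statistic is the
    standard two-sample chi-square with 1 df, no continuity correction.
    With no events in either group the test is undefined and p is None.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = pd.Series(groups)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise InvalidInputError(f"need exactly 2 groups, got {labels}")
    curves = {}
    for lab in labels:
        sel = (groups == lab).to_numpy()
        if sel.sum() == 0:
            raise InvalidInputError(f"empty group {lab}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel], label=str(lab))
        tab = kmf.event_table
        curves[lab] = pd.DataFrame({
            "time": tab.index.to_numpy(),
            "at_risk": tab["at_risk"].to_numpy(),
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
        })
    cutoff = np.nan
    if events.sum() == 0:
        return KMResult(groups, curves, None, None, cutoff)
    sel0 = (groups == labels[0]).to_numpy()
    res = logrank_test(times[sel0], times[~sel0],
                       events[sel0], events[~sel0])
    return KMResult(groups, curves, float(res.test_statistic),
                    float(res.p_value), cutoff)


def km_product_limit(times, events) -> pd.DataFrame:
    """Single-group product-limit table (time, at_risk, events, survival)."""
    order = np.lexsort((1 - np.asarray(events), np.asarray(times)))
    times = np.asarray(times, dtype=float)[order]
    events = np.asarray(events, dtype=int)[order]
    rows, surv, n = [], 1.0, len(times)
    for t in np.unique(times):
        at_risk = int((times >= t).sum())
        d = int(events[times == t].sum())
        if d > 0:
            surv *= (1 - d / at_risk)
        rows.append({"time": t, "at_risk": at_risk, "events": d,
                     "survival": surv})
    return pd.DataFrame(rows)


REQUIRED_CLINICAL_COLUMNS = ("patient_id", "cohort", "volume",
                             "interval_days", "followup_months", "event")


def _round_half_up(x: float, ndigits: int) -> float:
    # report-style rounding: 20.965 -> 20.97 (banker's rounding would not)
    from decimal import ROUND_HALF_UP, Decimal
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def cohort_summary(clinical: pd.DataFrame) -> pd.DataFrame:
    """Per-cohort collection-interval, follow-up and disease-volume summary.

    Reports the mean days between the two serial collections (1 decimal),
    the median and range of follow-up in months (2 decimals), and patient
    counts by metastatic volume status.
    """
    for col in REQUIRED_CLINICAL_COLUMNS:
        if col not in clinical.columns:
            raise InvalidInputError(f"missing clinical column: {col}")
    rows = []
    for cohort, sub in clinical.groupby("cohort"):
        fu = sub["followup_months"].astype(float)
        volumes = sub["volume"].value_counts().to_dict()
        rows.append({
            "cohort": cohort,
            "n_patients": len(sub),
            "mean_interval_days": _round_half_up(
                float(sub["interval_days"].mean()), 1),
            "median_followup_months": _round_half_up(float(fu.median()), 2),
            "min_followup_months": _round_half_up(float(fu.min()), 2),
            "max_followup_months": _round_half_up(float(fu.max()), 2),
            "n_high_volume": int(volumes.get("High Volume", 0)),
            "n_low_volume": int(volumes.get("Low Volume", 0)),
        })
    return pd.DataFrame(rows).set_index("cohort")


def load_clinical() -> pd.DataFrame:
    """Packaged clinical table for the 19-patient two-cohort study."""
    src = importlib.resources.files("urocnv.data") / "clinical_19pt.tsv"
    with importlib.resources.as_file(src) as path:
        return pd.read_csv(path, sep="\t")
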