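"""Continuous (epoch-free) recovery metrics and cohort comparison.

Treating the activity record as a continuous stream avoids the
categorization bias of epoch labels: the flagship metric is the proportion
of observed post-operative days on which smoothed activity exceeds the
patient's own pre-operative baseline mean.  Exceedance is judged on the
smoothed series — raw daily counts are noise-dominated.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import MetricsError
from .io import ActivitySeries
from .preprocessing import BaselineStats, NormalizedSeries
from .segmentation import EpochSegmentation

#: Metric names accepted by :func:`compare_cohorts`.
METRIC_FIELDS = (
    "proportion_above_baseline",
    "time_to_baseline_days",
    "total_improvement_z",
    "recovery_duration_days",
    "auc_z",
)


@dataclass(frozen=True)
class RecoveryMetrics:
    """Per-patient continuous recovery summary.

    ``auc_z`` is the net area of the post-operative smoothed z curve
    (SD·days above the individual baseline; one day per observation).
    """

    patient_id: str
    proportion_above_baseline: float
    time_to_baseline_days: int | None
    total_improvement_z: float
    recovery_duration_days: int | None
    auc_z: float

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "proportion_above_baseline": self.proportion_above_baseline,
            "time_to_baseline_days": self.time_to_baseline_days,
            "total_improvement_z": self.total_improvement_z,
            "recovery_duration_days": self.recovery_duration_days,
            "auc_z": self.auc_z,
        }


def compute_metrics(
    raw_smoothed: ActivitySeries,
    norm_smoothed: NormalizedSeries,
    baseline: BaselineStats,
    seg: EpochSegmentation | None = None,
) -> RecoveryMetrics:
    """Compute the continuous recovery metrics for one patient.

    All denominators count observed days only.  Raises
    :class:`MetricsError` (``no_postop_data``) when no post-operative day
    is observed.
    """
    raw_post = raw_smoothed.data[raw_smoothed.data.index > 0].dropna()
    z = norm_smoothed.data
    z_post = z[z.index > 0].dropna()
    z_pre = z[z.index < 0].dropna()
    if raw_post.empty or z_post.empty:
        raise MetricsError("no_postop_data")

    above = raw_post > baseline.mean
    proportion = float(above.mean())
    reaching = raw_post[raw_post >= baseline.mean]
    time_to_baseline = int(reaching.index.min()) if not reaching.empty else None
    total_improvement = float(z_post.mean() - z_pre.mean()) if len(z_pre) else float(
        z_post.mean()
    )
    rec = seg.get("immediate_postoperative_recovery") if seg is not None else None
    recovery_duration = rec.duration_days if rec is not None else None
    auc = float(z_post.sum())
    return RecoveryMetrics(
        patient_id=raw_smoothed.patient_id,
        proportion_above_baseline=proportion,
        time_to_baseline_days=time_to_baseline,
        total_improvement_z=total_improvement,
        recovery_duration_days=recovery_duration,
        auc_z=auc,
    )


def metrics_frame(metrics: Iterable[RecoveryMetrics]) -> pd.DataFrame:
    """One row per patient, ready for the metrics CSV."""
    return pd.DataFrame([m.to_dict() for m in metrics])


# ---------------------------------------------------------------------------
# Cohort comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortComparison:
    """Two-sided test summary for one metric across two cohorts."""

    metric: str
    method: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    mean_a: float
    mean_b: float
    direction: str  # "a_greater", "b_greater" or "equal" (by median)

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _values(metrics: Sequence[RecoveryMetrics], name: str) -> np.ndarray:
    if name not in METRIC_FIELDS:
        raise ValueError(f"unknown metric {name!r}; choose from {METRIC_FIELDS}")
    vals = [getattr(m, name) for m in metrics]
    return np.array([v for v in vals if v is not None], dtype=float)


def compare_cohorts(
    metrics_a: Sequence[RecoveryMetrics],
    metrics_b: Sequence[RecoveryMetrics],
    metric_name: str,
    method: str = "mann_whitney",
) -> CohortComparison:
    """Two-sided comparison of one recovery metric between two cohorts.

    Mann–Whitney U is the default (small cohorts, skewed durations);
    Welch's t is available.  Patients with an undefined value of the metric
    (e.g. no recovery epoch) are dropped from that comparison.
    """
    a = _values(metrics_a, metric_name)
    b = _values(metrics_b, metric_name)
    if len(a) < 2 or len(b) < 2:
        raise MetricsError(
            f"need >= 2 defined values per group for {metric_name!r} "
            f"(got {len(a)} and {len(b)})"
        )
    if method == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif method == "welch_t":
        res = stats.ttest_ind(a, b, equal_var=False)
    else:
        raise ValueError("method must be 'mann_whitney' or 'welch_t'")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if med_a > med_b:
        direction = "a_greater"
    elif med_b > med_a:
        direction = "b_greater"
    else:
        direction = "equal"
    return CohortComparison(
        metric=metric_name,
        method=method,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=len(a),
        n_b=len(b),
        median_a=med_a,
        median_b=med_b,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        direction=direction,
    )


def cohort_report(
    metrics_a: Sequence[RecoveryMetrics],
    metrics_b: Sequence[RecoveryMetrics],
    metric_names: Sequence[str],
    method: str = "mann_whitney",
    alpha: float = 0.05,
) -> dict:
    """Compare several metrics and apply Benjamini–Hochberg across them.

    Returns a JSON-ready dict; each comparison carries its raw and
    BH-adjusted p-value (the adjustment is disclosed in the output).
    """
    comparisons = [
        compare_cohorts(metrics_a, metrics_b, name, method) for name in metric_names
    ]
    pvals = [c.p_value for c in comparisons]
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return {
        "method": method,
        "multiple_testing_correction": "benjamini_hochberg",
        "alpha": alpha,
        "comparisons": [
            {**c.to_dict(), "p_adjusted": float(pa), "significant": bool(r)}
            for c, pa, r in zip(comparisons, p_adj, reject)
        ],
    }
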