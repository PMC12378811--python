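"""Perioperative window selection, QC, baseline normalization and smoothing.

The processing chain mirrors standard actigraphy practice for surgical
cohorts:

1.  keep one year before and one year after surgery (day 0 excluded, so a
    complete patient contributes 365 + 365 = 730 daily slots);
2.  require observed data spanning the whole window (eligibility);
3.  drop any 30-day "patient-month" block, anchored at surgery, whose
    fraction of missing-or-zero days is strictly greater than 20%;
4.  express each day as a z-score against the patient's own pre-operative
    baseline mean and SD (sample SD, ``n-1``), so a 1,000-step change means
    more for a sedentary 4,000-steps/day patient than for an active
    12,000-steps/day one;
5.  smooth with a centered 14-day moving average that ignores missing days.

All functions are pure: they return new series and never mutate inputs.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import DegenerateBaselineError, InsufficientBaselineError
from .io import ActivitySeries

# QC reason codes
REASON_PREOP_SPAN = "insufficient_preop_span"
REASON_POSTOP_SPAN = "insufficient_postop_span"


@dataclass(frozen=True)
class BaselineStats:
    """Individual baseline: mean and sample SD of observed baseline days."""

    mean: float
    sd: float
    n_days: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")


@dataclass
class NormalizedSeries:
    """Day-offset series in baseline SD units (z-scores).

    Carries the :class:`BaselineStats` used, so the raw scale can be
    reconstructed exactly (``raw = mean + sd * z``) — normalization and the
    moving average are both affine, so they commute.
    """

    patient_id: str
    metric: str
    data: pd.Series
    baseline: BaselineStats

    def __post_init__(self):
        self.data = pd.Series(self.data, dtype=float).sort_index()

    def to_raw(self) -> ActivitySeries:
        raw = self.baseline.mean + self.baseline.sd * self.data
        return ActivitySeries(self.patient_id, self.metric, raw.clip(lower=0))

    def replace(self, **kw) -> "NormalizedSeries":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class BlockRecord:
    """QC outcome for one patient-month block."""

    start_offset: int
    end_offset: int
    n_days: int
    missing_or_zero_fraction: float
    kept: bool


@dataclass
class QCReport:
    """Eligibility verdict plus the per-block missingness audit."""

    eligible: bool
    reasons: list[str] = field(default_factory=list)
    blocks: list[BlockRecord] = field(default_factory=list)

    @property
    def n_blocks_dropped(self) -> int:
        return sum(not b.kept for b in self.blocks)

    def to_dict(self) -> dict:
        return {
            "eligible": self.eligible,
            "reasons": list(self.reasons),
            "blocks": [
                {
                    "start_offset": b.start_offset,
                    "end_offset": b.end_offset,
                    "n_days": b.n_days,
                    "missing_or_zero_fraction": b.missing_or_zero_fraction,
                    "kept": b.kept,
                }
                for b in self.blocks
            ],
        }


# ---------------------------------------------------------------------------
# Window selection and eligibility
# ---------------------------------------------------------------------------

def select_window(series: ActivitySeries, config: PipelineConfig) -> ActivitySeries:
    """Restrict an aligned series to the perioperative analysis window.

    Keeps offsets in ``[-pre, -1] U [+1, +post]`` and reindexes onto the
    full slot grid (absent days become NaN).  Day 0, the surgery day, is
    excluded: in-hospital phone carry makes it uninterpretable, and the
    2-year default then yields exactly 730 candidate slots.
    """
    if not series.is_aligned:
        raise ValueError("series must be aligned to surgery first")
    slots = list(range(-config.pre_window_days, 0)) + list(
        range(1, config.post_window_days + 1)
    )
    data = series.data.reindex(pd.Index(slots, dtype=int))
    return series.replace(data=data)


def check_eligibility(series: ActivitySeries, config: PipelineConfig) -> QCReport:
    """Require observed data spanning the whole pre- and post-op windows.

    The earliest observed pre-op day must reach ``-pre_window_days`` and the
    latest observed post-op day must reach ``+post_window_days`` (zero
    tolerance, per the one-year-each-side inclusion rule).
    """
    obs = series.observed()
    pre = obs[obs.index < 0]
    post = obs[obs.index > 0]
    reasons = []
    if pre.empty or pre.index.min() > -config.pre_window_days:
        reasons.append(REASON_PREOP_SPAN)
    if post.empty or post.index.max() < config.post_window_days:
        reasons.append(REASON_POSTOP_SPAN)
    return QCReport(eligible=not reasons, reasons=reasons)


# ---------------------------------------------------------------------------
# Patient-month QC
# ---------------------------------------------------------------------------

def _blocks(config: PipelineConfig):
    """Patient-month partition of the window, anchored at surgery.

    Pre-op blocks: [-L,-1], [-2L,-L-1], ...; post-op: [+1,+L], [+L+1,+2L],
    ...  The far edge block is clipped to the window, so the partition
    covers every slot exactly once.
    """
    L = config.block_length_days
    out = []
    lo = -L
    while lo > -config.pre_window_days - L:
        start = max(lo, -config.pre_window_days)
        end = lo + L - 1
        if end >= start:
            out.append((start, end))
        lo -= L
    out.reverse()
    hi = 1
    while hi <= config.post_window_days:
        start = hi
        end = min(hi + L - 1, config.post_window_days)
        out.append((start, end))
        hi += L
    return out


def qc_block_filter(
    series: ActivitySeries, config: PipelineConfig
) -> tuple[ActivitySeries, QCReport]:
    """Apply the patient-month missing-or-zero rule to a windowed series.

    A block whose missing-or-zero fraction is *strictly* greater than
    ``max_missing_fraction`` has all its days set to missing.  Zeros count
    toward exclusion (when ``zero_is_missing_for_qc``) but retained zeros
    stay zeros — nothing is imputed.
    """
    data = series.data.copy()
    records = []
    for start, end in _blocks(config):
        chunk = data.loc[start:end]
        n = int(len(chunk))
        if n == 0:
            continue
        n_missing = int(chunk.isna().sum())
        if config.zero_is_missing_for_qc:
            n_missing += int((chunk == 0).sum())
        frac = n_missing / n
        kept = frac <= config.max_missing_fraction
        if not kept:
            data.loc[start:end] = np.nan
        records.append(BlockRecord(start, end, n, frac, kept))
    report = QCReport(eligible=True, blocks=records)
    return series.replace(data=data), report


# ---------------------------------------------------------------------------
# Baseline and normalization
# ---------------------------------------------------------------------------

def compute_baseline(
    series: ActivitySeries, config: PipelineConfig
) -> BaselineStats:
    """Mean and sample SD of observed days in the baseline window.

    The default window [-365, -91] deliberately stops 90 days before
    surgery so the acute pre-operative decline does not contaminate the
    reference level.
    """
    lo, hi = config.baseline_window
    vals = series.data.loc[lo:hi].dropna()
    if len(vals) < 2:
        raise InsufficientBaselineError(
            f"only {len(vals)} observed day(s) in baseline window [{lo}, {hi}]"
        )
    return BaselineStats(
        mean=float(vals.mean()), sd=float(vals.std(ddof=1)), n_days=int(len(vals))
    )


def normalize(series: ActivitySeries, baseline: BaselineStats) -> NormalizedSeries:
    """Express each observed day in baseline SD units; missing stays missing."""
    if baseline.sd <= 0:
        raise DegenerateBaselineError(
            "baseline SD is zero; z-normalization undefined"
        )
    z = (series.data - baseline.mean) / baseline.sd
    return NormalizedSeries(series.patient_id, series.metric, z, baseline)


# ---------------------------------------------------------------------------
# Moving-average smoothing
# ---------------------------------------------------------------------------

def moving_average(values: np.ndarray, window: int, centered: bool = True) -> np.ndarray:
    """Missingness-aware moving mean over a contiguous daily array.

    For an even centered window ``w`` the day-``t`` window is
    ``[t - w/2, t + w/2 - 1]`` (14 days -> t-7 .. t+6); odd windows are
    symmetric.  NaNs are excluded from each mean; a window with no observed
    day yields NaN; edges use the truncated window.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if window < 1:
        raise ValueError("window must be >= 1")
    if centered:
        left = window // 2
        right = window - 1 - left
    else:
        left, right = window - 1, 0
    obs = ~np.isnan(values)
    filled = np.where(obs, values, 0.0)
    csum = np.concatenate(([0.0], np.cumsum(filled)))
    ccnt = np.concatenate(([0], np.cumsum(obs.astype(np.int64))))
    idx = np.arange(n)
    lo = np.clip(idx - left, 0, n)
    hi = np.clip(idx + right + 1, 0, n)
    cnt = ccnt[hi] - ccnt[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(cnt > 0, (csum[hi] - csum[lo]) / np.maximum(cnt, 1), np.nan)
    return out


def smooth(series, config: PipelineConfig):
    """Smooth a series with the configured moving average.

    Accepts an :class:`ActivitySeries` or :class:`NormalizedSeries` and
    returns the same type on the same day slots.  Internally the series is
    placed on a contiguous daily grid (so true calendar gaps, e.g. the
    excluded surgery day, count as missing inside windows) and the
    missingness-aware mean of :func:`moving_average` is applied.
    """
    data = series.data
    if len(data) == 0:
        return series.replace(data=data.copy())
    full = pd.RangeIndex(int(data.index.min()), int(data.index.max()) + 1)
    dense = data.reindex(full)
    sm = moving_average(
        dense.to_numpy(), config.smoothing_window_days, config.smoothing_centered
    )
    out = pd.Series(sm, index=full).reindex(data.index)
    return series.replace(data=out)
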