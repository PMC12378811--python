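"""Rule-based segmentation of the perioperative course into five epochs.

The smoothed z-score trajectory is scanned deterministically for the five
named phases of surgical recovery:

``preoperative_baseline``
    the observed part of the baseline window;
``acute_preoperative_decline``
    the longest pre-operative run with z at or below the negative change
    threshold, lasting at least the minimum epoch length;
``immediate_postoperative_recovery``
    from the post-operative nadir to full-recovery onset (or, when full
    recovery is never reached, to the last new running maximum before the
    climb stalls);
``full_recovery``
    sustained activity at least (1 + 0.8) x the patient's baseline mean
    (default literal reading of "80% improvement above baseline");
``secondary_decline``
    a later sustained drop of at least the change threshold below the
    established full-recovery level.

Rule-based scanning (rather than generic change-point detection) keeps
every boundary attributable to a stated, configurable rule.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import SegmentationError
from .preprocessing import BaselineStats, NormalizedSeries

EPOCH_LABELS = (
    "preoperative_baseline",
    "acute_preoperative_decline",
    "immediate_postoperative_recovery",
    "full_recovery",
    "secondary_decline",
)


@dataclass(frozen=True)
class Epoch:
    """One labeled phase with inclusive day-offset bounds and statistics."""

    label: str
    start_offset: int
    end_offset: int
    mean_z: float | None = None
    slope: float | None = None  # SD units per day; None if < 2 observed days
    magnitude: float | None = None  # mean_z minus baseline-epoch mean_z
    slope_defined: bool = True

    def __post_init__(self):
        if self.label not in EPOCH_LABELS:
            raise ValueError(f"unknown epoch label {self.label!r}")
        if self.start_offset > self.end_offset:
            raise ValueError("epoch start must not exceed end")

    @property
    def duration_days(self) -> int:
        return self.end_offset - self.start_offset + 1

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "start_offset": self.start_offset,
            "end_offset": self.end_offset,
            "duration_days": self.duration_days,
            "mean_z": self.mean_z,
            "slope": self.slope,
            "slope_defined": self.slope_defined,
            "magnitude": self.magnitude,
        }


@dataclass
class EpochSegmentation:
    """Ordered, non-overlapping epochs for one patient."""

    patient_id: str
    epochs: list[Epoch] = field(default_factory=list)
    full_recovery_achieved: bool = False
    secondary_decline_present: bool = False

    def get(self, label: str) -> Epoch | None:
        for e in self.epochs:
            if e.label == label:
                return e
        return None

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "full_recovery_achieved": self.full_recovery_achieved,
            "secondary_decline_present": self.secondary_decline_present,
            "epochs": [e.to_dict() for e in self.epochs],
        }


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _runs(index: np.ndarray, mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive day offsets where ``mask`` holds.

    A run breaks on a False day *or* on a gap in the day-offset index.
    """
    out: list[tuple[int, int]] = []
    start = prev = None
    for off, ok in zip(index, mask):
        if ok:
            if start is None:
                start = prev = int(off)
            elif int(off) == prev + 1:
                prev = int(off)
            else:
                out.append((start, prev))
                start = prev = int(off)
        else:
            if start is not None:
                out.append((start, prev))
                start = prev = None
    if start is not None:
        out.append((start, prev))
    return out


def _observed(series: pd.Series, lo: int, hi: int) -> pd.Series:
    return series.loc[lo:hi].dropna()


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def classify_full_recovery(
    norm_smoothed: NormalizedSeries,
    baseline: BaselineStats,
    config: PipelineConfig,
) -> tuple[bool, int | None]:
    """Decide whether the patient reached sustained full recovery.

    Default mode (``relative_to_baseline``, the literal reading): smoothed
    raw-scale activity must be at least ``(1 + f) x baseline.mean`` — with
    the default f = 0.8, 1.8x baseline — for ``sustained_days`` consecutive
    observed days.  Alternative mode (``fraction_of_nadir_gap``): activity
    must close at least fraction ``f`` of the nadir-to-baseline gap.
    Returns ``(achieved, onset_offset)``; onset is the first day of the
    first qualifying run, or None.
    """
    z = norm_smoothed.data
    raw = baseline.mean + baseline.sd * z
    post = raw[raw.index > 0]
    obs = post.dropna()
    if obs.empty:
        return False, None
    if config.recovery_mode == "relative_to_baseline":
        threshold = (1.0 + config.sustained_improvement_fraction) * baseline.mean
    else:
        n_lo, n_hi = config.nadir_window
        nadir_vals = _observed(post, n_lo, n_hi)
        nadir = float(nadir_vals.min()) if not nadir_vals.empty else float(obs.min())
        threshold = nadir + config.sustained_improvement_fraction * (
            baseline.mean - nadir
        )
    mask = (post >= threshold) & post.notna()
    for start, end in _runs(post.index.to_numpy(), mask.to_numpy()):
        if end - start + 1 >= config.sustained_days:
            return True, start
    return False, None


def quantify_epoch(
    norm_smoothed: NormalizedSeries,
    epoch: Epoch,
    baseline_mean_z: float = 0.0,
) -> Epoch:
    """Fill duration-independent statistics: mean z, least-squares slope,
    and magnitude relative to the baseline epoch mean.

    With fewer than 2 observed days the slope is flagged undefined; the
    duration is still reported from the bounds.
    """
    obs = _observed(norm_smoothed.data, epoch.start_offset, epoch.end_offset)
    mean_z = float(obs.mean()) if len(obs) else None
    if len(obs) >= 2:
        slope = float(np.polyfit(obs.index.to_numpy(float), obs.to_numpy(), 1)[0])
        slope_defined = True
    else:
        slope, slope_defined = None, False
    magnitude = None if mean_z is None else mean_z - baseline_mean_z
    return replace(
        epoch,
        mean_z=mean_z,
        slope=slope,
        slope_defined=slope_defined,
        magnitude=magnitude,
    )


def _recovery_end_by_stall(
    post: pd.Series, nadir_off: int, config: PipelineConfig
) -> int:
    """End of the recovery climb when the sustained-recovery criterion is
    never met: the last day a new running maximum is set before the first
    stretch of more than ``min_epoch_days`` without a new maximum.
    """
    seg = post.loc[nadir_off:].dropna()
    best = -np.inf
    records = []
    for off, val in seg.items():
        if val > best:
            best = val
            records.append(int(off))
    end = records[-1]
    for a, b in zip(records, records[1:]):
        if b - a > config.min_epoch_days:
            end = a
            break
    return end


def segment_epochs(
    norm_smoothed: NormalizedSeries, config: PipelineConfig
) -> EpochSegmentation:
    """Segment a smoothed, normalized series into the five epochs.

    The scan is deterministic; ties in the nadir search break to the
    earliest day.  Raises :class:`SegmentationError` (``no_postop_data``)
    when no post-operative day is observed.
    """
    z = norm_smoothed.data
    baseline = norm_smoothed.baseline
    post = z[z.index > 0]
    if post.dropna().empty:
        raise SegmentationError("no_postop_data")

    epochs: list[Epoch] = []

    # 1 — preoperative baseline: observed part of the baseline window
    b_lo, b_hi = config.baseline_window
    base_obs = _observed(z, b_lo, b_hi)
    baseline_mean_z = 0.0
    if not base_obs.empty:
        ep = Epoch(
            "preoperative_baseline",
            int(base_obs.index.min()),
            int(base_obs.index.max()),
        )
        ep = quantify_epoch(norm_smoothed, ep, baseline_mean_z=0.0)
        baseline_mean_z = ep.mean_z if ep.mean_z is not None else 0.0
        ep = replace(ep, magnitude=0.0)
        epochs.append(ep)

    # 2 — acute preoperative decline: longest qualifying sub-threshold run
    a_lo, a_hi = config.acute_preop_window
    acute = z.loc[a_lo:a_hi]
    mask = (acute <= -config.sd_change_threshold) & acute.notna()
    candidates = [
        (s, e)
        for s, e in _runs(acute.index.to_numpy(), mask.to_numpy())
        if e - s + 1 >= config.min_epoch_days
    ]
    if candidates:
        start, end = max(candidates, key=lambda r: (r[1] - r[0], -r[0]))
        epochs.append(
            quantify_epoch(
                norm_smoothed,
                Epoch("acute_preoperative_decline", start, end),
                baseline_mean_z,
            )
        )

    # 3 — post-operative nadir and the full-recovery call
    n_lo, n_hi = config.nadir_window
    nadir_obs = _observed(post, n_lo, n_hi)
    if nadir_obs.empty:
        nadir_obs = post.dropna()
    nadir_off = int(nadir_obs.idxmin())  # first occurrence on ties
    nadir_z = float(nadir_obs.loc[nadir_off])

    achieved, onset = classify_full_recovery(norm_smoothed, baseline, config)

    # immediate postoperative recovery requires an actual dip to recover from
    if nadir_z <= -config.sd_change_threshold and not (
        achieved and onset is not None and onset <= nadir_off
    ):
        if achieved and onset is not None:
            rec_end = onset - 1
        else:
            rec_end = _recovery_end_by_stall(post, nadir_off, config)
        if rec_end >= nadir_off:
            epochs.append(
                quantify_epoch(
                    norm_smoothed,
                    Epoch("immediate_postoperative_recovery", nadir_off, rec_end),
                    baseline_mean_z,
                )
            )

    # 4 + 5 — full recovery and any later secondary decline
    secondary_present = False
    if achieved and onset is not None:
        last_obs = int(post.dropna().index.max())
        # reference level from the qualifying window only, so a later
        # decline cannot drag the reference down (see methods note)
        ref_win = _observed(post, onset, onset + config.sustained_days - 1)
        ref = float(ref_win.mean())
        search = post.loc[onset + config.sustained_days :]
        smask = (search <= ref - config.sd_change_threshold) & search.notna()
        sec_run = None
        for s, e in _runs(search.index.to_numpy(), smask.to_numpy()):
            if e - s + 1 >= config.min_epoch_days:
                sec_run = (s, e)
                break
        full_end = last_obs if sec_run is None else sec_run[0] - 1
        if full_end >= onset:
            epochs.append(
                quantify_epoch(
                    norm_smoothed,
                    Epoch("full_recovery", onset, full_end),
                    baseline_mean_z,
                )
            )
        if sec_run is not None:
            secondary_present = True
            epochs.append(
                quantify_epoch(
                    norm_smoothed,
                    Epoch("secondary_decline", sec_run[0], sec_run[1]),
                    baseline_mean_z,
                )
            )

    order = {label: i for i, label in enumerate(EPOCH_LABELS)}
    epochs.sort(key=lambda e: order[e.label])
    return EpochSegmentation(
        patient_id=norm_smoothed.patient_id,
        epochs=epochs,
        full_recovery_achieved=achieved,
        secondary_decline_present=secondary_present,
    )
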