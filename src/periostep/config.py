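"""Pipeline configuration.

Every numeric rule of the analysis lives in :class:`PipelineConfig` so that a
run is fully described by one object: the perioperative window, the QC
block rule, the baseline window used for z-normalization, the smoothing
window, and the epoch-detection thresholds.  Defaults follow the published
methodology where it states a value (one year pre/post, 14-day moving
average, >20% missing-or-zero patient-months, sustained 80% improvement)
and this package's documented choices where it does not (the 0.5 SD change
threshold, 14-day minimum epoch length, 28-day sustainment).
"""
from __future__ import annotations

from typing import Literal, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

DayWindow = Tuple[int, int]


class PipelineConfig(BaseModel):
    """All tunable rules of the perioperative activity pipeline.

    Windows are inclusive ``(start, end)`` day-offset intervals relative to
    surgery (day 0); negative offsets are pre-operative.
    """

    model_config = ConfigDict(frozen=True)

    #: Days of pre-operative data required/retained (offsets -pre..-1).
    pre_window_days: int = Field(default=365, ge=1)
    #: Days of post-operative data required/retained (offsets +1..+post).
    post_window_days: int = Field(default=365, ge=1)
    #: Width of the moving-average smoother, in days.
    smoothing_window_days: int = Field(default=14, ge=1)
    #: Length of the "patient-month" QC block, anchored at surgery.
    block_length_days: int = Field(default=30, ge=1)
    #: A QC block with missing-or-zero fraction strictly above this is dropped.
    max_missing_fraction: float = Field(default=0.20, gt=0.0, lt=1.0)
    #: Window whose observed days define the individual baseline mean/SD.
    baseline_window: DayWindow = (-365, -91)
    #: Window scanned for the acute pre-operative decline epoch.
    acute_preop_window: DayWindow = (-90, -1)
    #: Epoch-detection threshold for activity change, in baseline SD units.
    sd_change_threshold: float = Field(default=0.5, gt=0.0)
    #: Minimum run length, in days, for a decline epoch to count.
    min_epoch_days: int = Field(default=14, ge=1)
    #: "80% improvement above baseline" fraction for the full-recovery call.
    sustained_improvement_fraction: float = Field(default=0.80, gt=0.0)
    #: Consecutive days the improvement must hold to count as sustained.
    sustained_days: int = Field(default=28, ge=1)
    #: Reading of the full-recovery criterion (literal 1.8x baseline, or
    #: fraction of the nadir-to-baseline gap closed).
    recovery_mode: Literal["relative_to_baseline", "fraction_of_nadir_gap"] = (
        "relative_to_baseline"
    )
    #: Whether zero-activity days count as missing for the QC block rule.
    zero_is_missing_for_qc: bool = True
    #: Whether retained zero-activity days are masked to missing before
    #: normalization/smoothing/segmentation.  Passively recorded zeros are
    #: indistinguishable from the phone being left at home; a single true
    #: zero inside a 14-day window can otherwise fake a sustained decline.
    zero_is_missing_for_analysis: bool = True
    #: Window searched for the post-operative nadir.
    nadir_window: DayWindow = (1, 90)
    #: Centered (True) vs trailing (False) moving average.
    smoothing_centered: bool = True
    #: Whether a secondary decline must follow full-recovery onset (default)
    #: or merely the immediate-postoperative-recovery epoch.
    secondary_decline_requires_full_recovery: bool = True

    @model_validator(mode="after")
    def _check_windows(self) -> "PipelineConfig":
        for name in ("baseline_window", "acute_preop_window", "nadir_window"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is empty: ({lo}, {hi})")
        b0, b1 = self.baseline_window
        a0, a1 = self.acute_preop_window
        if not (b1 < a0 or a1 < b0):
            raise ValueError(
                "baseline_window and acute_preop_window must be disjoint"
            )
        if b0 < -self.pre_window_days:
            raise ValueError("baseline_window extends beyond pre_window_days")
        return self

    # -- serialization ----------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a config from a YAML mapping file; absent keys use defaults."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        for key in ("baseline_window", "acute_preop_window", "nadir_window"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.snapshot(), fh, sort_keys=True)

    def snapshot(self) -> dict:
        """JSON/YAML-safe dict of every rule, for run manifests."""
        d = self.model_dump()
        for key in ("baseline_window", "acute_preop_window", "nadir_window"):
            d[key] = list(d[key])
        return d
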