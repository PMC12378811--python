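"""Synthetic perioperative activity cohorts with planted ground truth.

The generator emulates the canonical five-phase surgical trajectory: a
stable individual baseline (sedentary ~4,000 to active ~12,000 steps/day),
an acute pre-operative decline, a post-operative nadir, a recovery ramp to
a plateau, and an optional later secondary decline.  On top of the
piecewise-linear mean curve sit Gaussian day-to-day noise (truncated at
zero), a weekday/weekend sinusoid, and missing-day / zero-day processes.
Every draw is a deterministic function of the scenario seed, and the
planted structure is returned as :class:`GroundTruth` so every pipeline
stage can be scored against it.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .config import PipelineConfig
from .errors import ScenarioError
from .io import ActivitySeries, PatientProfile

#: Days over which a planted secondary decline ramps down to its new level.
SECONDARY_RAMP_DAYS = 14


@dataclass(frozen=True)
class SimScenario:
    """Ground-truth parameters of one synthetic patient trajectory.

    Levels (``nadir_level``, ``recovery_plateau``, decline depths) are
    fractions of ``baseline_mean``; offsets are days relative to surgery.
    """

    baseline_mean: float = 4000.0
    baseline_sd: float = 800.0  # day-to-day noise SD, steps
    weekly_amplitude: float = 400.0  # day-of-week sinusoid, steps
    preop_decline_start: int = -60
    preop_decline_depth: float = 0.30  # level at day 0- is baseline*(1-depth)
    nadir_offset: int = 10
    nadir_level: float = 0.40
    recovery_end_offset: int = 120
    recovery_plateau: float = 2.0  # >1 means improvement over baseline
    secondary_decline: tuple[int, float] | None = None  # (start_offset, depth)
    missing_rate: float = 0.05
    zero_rate: float = 0.02
    missing_mode: str = "iid"  # or "burst"
    burst_mean_length: float = 5.0
    pre_days: int = 365
    post_days: int = 365
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.nadir_level < self.recovery_plateau):
            raise ScenarioError("require 0 < nadir_level < recovery_plateau")
        if not (
            self.preop_decline_start < 0 < self.nadir_offset < self.recovery_end_offset
        ):
            raise ScenarioError(
                "require decline_start < 0 < nadir_offset < recovery_end_offset"
            )
        for name in ("missing_rate", "zero_rate"):
            r = getattr(self, name)
            if not (0 <= r < 1):
                raise ScenarioError(f"{name} must be in [0, 1)")
        if not (0 <= self.preop_decline_depth < 1):
            raise ScenarioError("preop_decline_depth must be in [0, 1)")
        if self.secondary_decline is not None:
            start, depth = self.secondary_decline
            if start <= self.recovery_end_offset:
                raise ScenarioError("secondary decline must start after recovery end")
            if depth <= 0:
                raise ScenarioError("secondary decline depth must be positive")
        if self.baseline_sd < 0 or self.weekly_amplitude < 0:
            raise ScenarioError("noise parameters must be non-negative")
        if self.missing_mode not in ("iid", "burst"):
            raise ScenarioError("missing_mode must be 'iid' or 'burst'")

    # -- mean curve -------------------------------------------------------
    def mean_curve(self, t) -> np.ndarray:
        """Planted noise-free mean activity at day offset(s) ``t``."""
        b = self.baseline_mean
        xs = [
            self.preop_decline_start,
            0,
            self.nadir_offset,
            self.recovery_end_offset,
        ]
        ys = [
            b,
            b * (1 - self.preop_decline_depth),
            b * self.nadir_level,
            b * self.recovery_plateau,
        ]
        if self.secondary_decline is not None:
            start, depth = self.secondary_decline
            xs += [start, start + SECONDARY_RAMP_DAYS]
            ys += [b * self.recovery_plateau, b * (self.recovery_plateau - depth)]
        return np.interp(np.asarray(t, dtype=float), xs, ys)

    @property
    def effective_noise_sd(self) -> float:
        """SD of (noise + weekly sinusoid), the scale normalization sees."""
        return math.sqrt(self.baseline_sd**2 + self.weekly_amplitude**2 / 2.0)


@dataclass
class GroundTruth:
    """Planted structure of a simulated patient, for scoring detections."""

    scenario: SimScenario
    declined: bool
    missing_mask: pd.Series  # bool per day offset (True = missing)
    zero_mask: pd.Series
    planted_duration_days: int = 0  # nadir -> recovery-end ramp length

    def expected_boundaries(self, config: PipelineConfig) -> dict:
        """Day offsets where the detection rules should fire on the planted
        mean curve, computed in closed form from the piecewise-linear
        trajectory and the scenario's effective noise SD.

        Keys (value None when the rule should not fire):
        ``decline_onset`` — first day the mean curve drops to
        ``sd_change_threshold`` SDs below baseline; ``nadir`` — planted
        nadir; ``recovery_onset`` — first day the mean curve reaches
        ``(1+f) x baseline``; ``secondary_start`` — planted decline start.
        """
        s = self.scenario
        sd = s.effective_noise_sd
        b = s.baseline_mean
        out: dict[str, int | None] = {
            "nadir": s.nadir_offset,
            "decline_onset": None,
            "recovery_onset": None,
            "secondary_start": None,
        }
        # pre-op ramp: b -> b*(1-depth) over [decline_start, 0]
        drop_target = b - config.sd_change_threshold * sd
        level0 = b * (1 - s.preop_decline_depth)
        if sd > 0 and level0 <= drop_target:
            frac = (b - drop_target) / (b - level0)
            out["decline_onset"] = int(
                math.ceil(s.preop_decline_start * (1 - frac))
            )
        # recovery ramp: b*nadir_level -> b*plateau over [nadir, recovery_end]
        target = (1 + config.sustained_improvement_fraction) * b
        top = b * s.recovery_plateau
        bottom = b * s.nadir_level
        if top >= target:
            frac = (target - bottom) / (top - bottom)
            out["recovery_onset"] = int(
                math.ceil(s.nadir_offset + frac * (s.recovery_end_offset - s.nadir_offset))
            )
        if s.secondary_decline is not None:
            out["secondary_start"] = int(s.secondary_decline[0])
        return out


def _missing_mask(rng: np.random.Generator, n: int, scenario: SimScenario) -> np.ndarray:
    if scenario.missing_rate == 0:
        return np.zeros(n, dtype=bool)
    if scenario.missing_mode == "iid":
        return rng.random(n) < scenario.missing_rate
    # burst mode: geometric run lengths, matched overall rate
    mask = np.zeros(n, dtype=bool)
    p_start = scenario.missing_rate / scenario.burst_mean_length
    i = 0
    while i < n:
        if rng.random() < p_start:
            run = 1 + rng.geometric(1.0 / scenario.burst_mean_length)
            mask[i : i + run] = True
            i += run
        else:
            i += 1
    return mask


def simulate_patient(
    scenario: SimScenario,
    patient_id: str = "sim",
    surgery_date: date = date(2022, 6, 15),
) -> tuple[ActivitySeries, GroundTruth]:
    """Draw one synthetic aligned daily step series plus its ground truth.

    Daily value = ``max(0, mean_curve + N(0, sd) + weekly sinusoid)``; the
    missing mask removes days entirely and the zero mask records a kept day
    as 0 (phone left at home).  Identical seeds give identical output.
    """
    rng = np.random.default_rng(scenario.seed)
    offsets = np.arange(-scenario.pre_days, scenario.post_days + 1)
    n = len(offsets)
    mean = scenario.mean_curve(offsets)
    noise = rng.normal(0.0, scenario.baseline_sd, n) if scenario.baseline_sd else 0.0
    weekly = scenario.weekly_amplitude * np.sin(2 * np.pi * offsets / 7.0)
    values = np.maximum(0.0, mean + noise + weekly)
    missing = _missing_mask(rng, n, scenario)
    zero = (~missing) & (rng.random(n) < scenario.zero_rate)
    values[zero] = 0.0
    data = pd.Series(values, index=pd.Index(offsets, dtype=int))
    data[missing] = np.nan
    series = ActivitySeries(patient_id, "steps", data, surgery_date=surgery_date)
    truth = GroundTruth(
        scenario=scenario,
        declined=scenario.secondary_decline is not None,
        missing_mask=pd.Series(missing, index=data.index),
        zero_mask=pd.Series(zero, index=data.index),
        planted_duration_days=scenario.recovery_end_offset - scenario.nadir_offset,
    )
    return series, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Default cohort-level parameter ranges (uniform draws unless noted).
DEFAULT_RANGES: dict = {
    "baseline_mean": (4000.0, 12000.0),
    "noise_cv": 0.20,  # baseline_sd = cv * baseline_mean
    "weekly_cv": 0.10,  # weekly_amplitude = cv * baseline_mean
    "preop_decline_start": (-75, -45),
    "preop_decline_depth": (0.25, 0.40),
    "nadir_offset": (7, 21),
    "nadir_level": (0.30, 0.55),
    "recovery_end_offset": (80, 200),
    # plateau is a responder/non-responder mixture: most patients exceed the
    # 1.8x full-recovery bar, a minority plateau below their baseline gain
    "responder_fraction": 0.80,
    "responder_plateau": (1.90, 2.30),
    "nonresponder_plateau": (1.10, 1.50),
    "secondary_depth": (0.60, 0.90),
    "missing_rate": 0.05,
    "zero_rate": 0.02,
}


@dataclass
class SimCohort:
    series: list[ActivitySeries]
    profiles: list[PatientProfile]
    truths: list[GroundTruth]

    def __len__(self) -> int:
        return len(self.series)


def _calibrate_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Intercept b0 with mean(sigmoid(b0 + eta)) == prevalence."""
    f = lambda b0: float(np.mean(expit(b0 + eta))) - prevalence
    return brentq(f, -30.0, 30.0)


def simulate_cohort(
    n: int,
    scenario_ranges: dict | None = None,
    decline_prevalence: float = 0.30,
    effect_spec: dict[str, float] | None = None,
    seed: int = 0,
) -> SimCohort:
    """Simulate a cohort with planted decline labels.

    Per-patient scenarios are drawn from ``scenario_ranges`` (missing keys
    fall back to :data:`DEFAULT_RANGES`).  Decline labels come from a
    logistic model on standardized planted features — ``effect_spec`` maps
    ``{"recovery_duration_days" | "age" | "bmi": beta}`` — whose intercept
    is calibrated so the expected prevalence matches
    ``decline_prevalence``; labeled decliners get a secondary decline
    planted in their trajectory.
    """
    if n < 1:
        raise ScenarioError("n must be >= 1")
    if not (0 <= decline_prevalence < 1):
        raise ScenarioError("decline_prevalence must be in [0, 1)")
    ranges = dict(DEFAULT_RANGES)
    if scenario_ranges:
        ranges.update(scenario_ranges)
    rng = np.random.default_rng(seed)

    def u(key) -> np.ndarray:
        spec = ranges[key]
        if isinstance(spec, tuple):
            lo, hi = spec
            return rng.uniform(lo, hi, n)
        return np.full(n, float(spec))

    baseline_mean = u("baseline_mean")
    decline_start = np.round(u("preop_decline_start")).astype(int)
    decline_depth = u("preop_decline_depth")
    nadir_offset = np.round(u("nadir_offset")).astype(int)
    nadir_level = u("nadir_level")
    recovery_end = np.round(u("recovery_end_offset")).astype(int)
    responder = rng.random(n) < float(ranges["responder_fraction"])
    plat_hi = u("responder_plateau")
    plat_lo = u("nonresponder_plateau")
    plateau = np.where(responder, plat_hi, plat_lo)
    missing_rate = u("missing_rate")
    zero_rate = u("zero_rate")

    # clinical covariates
    age = np.clip(rng.normal(60.0, 12.0, n), 30.0, 85.0)
    bmi = np.clip(rng.normal(29.0, 5.0, n), 17.0, 45.0)
    cci = rng.poisson(1.5, n)
    procedure = rng.choice(["fusion", "decompression"], size=n)

    # planted decline labels from a logistic model on standardized features
    planted = {
        "recovery_duration_days": (recovery_end - nadir_offset).astype(float),
        "age": age,
        "bmi": bmi,
    }
    eta = np.zeros(n)
    if effect_spec:
        for name, beta in effect_spec.items():
            if name not in planted:
                raise ScenarioError(
                    f"effect_spec feature {name!r} not in {sorted(planted)}"
                )
            x = planted[name]
            sdx = x.std(ddof=0)
            zx = (x - x.mean()) / sdx if sdx > 0 else np.zeros(n)
            eta += beta * zx
    if decline_prevalence == 0:
        declined = np.zeros(n, dtype=bool)
    else:
        b0 = _calibrate_intercept(eta, decline_prevalence)
        declined = rng.random(n) < expit(b0 + eta)

    series_list, profiles, truths = [], [], []
    post_days = 365
    for i in range(n):
        secondary = None
        if declined[i]:
            lo = recovery_end[i] + 45
            hi = post_days - 45
            start = int(rng.integers(lo, max(hi, lo + 1)))
            depth = float(rng.uniform(*ranges["secondary_depth"]))
            secondary = (start, depth)
        scenario = SimScenario(
            baseline_mean=float(baseline_mean[i]),
            baseline_sd=float(ranges["noise_cv"]) * float(baseline_mean[i]),
            weekly_amplitude=float(ranges["weekly_cv"]) * float(baseline_mean[i]),
            preop_decline_start=int(decline_start[i]),
            preop_decline_depth=float(decline_depth[i]),
            nadir_offset=int(nadir_offset[i]),
            nadir_level=float(nadir_level[i]),
            recovery_end_offset=int(recovery_end[i]),
            recovery_plateau=float(plateau[i]),
            secondary_decline=secondary,
            missing_rate=float(missing_rate[i]),
            zero_rate=float(zero_rate[i]),
            seed=int(rng.integers(0, 2**31)),
        )
        pid = f"sim{i:04d}"
        s, t = simulate_patient(scenario, patient_id=pid)
        series_list.append(s)
        truths.append(t)
        profiles.append(
            PatientProfile(
                patient_id=pid,
                surgery_date=date(2022, 6, 15),
                age=float(age[i]),
                bmi=float(bmi[i]),
                cci=int(cci[i]),
                procedure=str(procedure[i]),
            )
        )
    return SimCohort(series_list, profiles, truths)
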