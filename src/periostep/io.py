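"""Reading and writing activity exports and cohort metadata.

Activity exports are HealthKit-style long tables: one row per
``(patient, timestamp, metric)`` with a non-negative value.  Timestamps are
taken as local wall-clock time and aggregation groups by the local calendar
date, matching how phone health databases report daily totals.  The
canonical on-disk form after alignment is the *aligned-series CSV* with
columns ``patient_id,day_offset,metric,value`` (missing days omitted).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateDayError,
    ExportValidationError,
    MixedSeriesError,
    SchemaError,
)

#: The three mobility metrics a phone health API exports.
METRICS = ("steps", "distance_m", "flights")
#: Accepted spellings in input files -> canonical metric name.
METRIC_ALIASES = {
    "steps": "steps",
    "step_count": "steps",
    "distance": "distance_m",
    "distance_m": "distance_m",
    "distance_km": "distance_m",
    "flights": "flights",
    "flights_climbed": "flights",
}
PROCEDURES = ("fusion", "decompression", "other")

DEFAULT_SCHEMA = {
    "patient_id": "patient_id",
    "timestamp": "timestamp",
    "metric": "metric",
    "value": "value",
}


@dataclass(frozen=True)
class RawActivityRecord:
    """One exported measurement (typically an hourly bucket)."""

    patient_id: str
    timestamp: datetime
    metric: str
    value: float

    def __post_init__(self):
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if not (self.value >= 0):
            raise ValueError(f"negative value {self.value!r}")


@dataclass(frozen=True)
class PatientProfile:
    """Clinical covariates used downstream for decline prediction."""

    patient_id: str
    surgery_date: date
    age: float
    bmi: float
    cci: int
    procedure: str

    def __post_init__(self):
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.bmi <= 0:
            raise ValueError("bmi must be positive")
        if self.cci < 0:
            raise ValueError("cci must be non-negative")
        if self.procedure not in PROCEDURES:
            raise ValueError(f"unknown procedure {self.procedure!r}")


@dataclass
class ActivitySeries:
    """A per-patient daily series for one metric.

    ``data`` is a float Series with NaN for missing days.  Before alignment
    the index is a normalized ``DatetimeIndex`` of calendar dates; after
    :func:`align_to_surgery` it is an integer index of day offsets relative
    to surgery (day 0 = surgery date, negative = pre-operative).
    """

    patient_id: str
    metric: str
    data: pd.Series
    surgery_date: date | None = None

    def __post_init__(self):
        s = pd.Series(self.data, dtype=float)
        if s.index.has_duplicates:
            raise DuplicateDayError(
                f"duplicate day keys for patient {self.patient_id!r}"
            )
        s = s.sort_index()
        with np.errstate(invalid="ignore"):
            if (s.dropna() < 0).any():
                raise ValueError("activity values must be non-negative")
        self.data = s

    @property
    def is_aligned(self) -> bool:
        return pd.api.types.is_integer_dtype(self.data.index)

    @property
    def n_observed(self) -> int:
        return int(self.data.notna().sum())

    def observed(self) -> pd.Series:
        return self.data.dropna()

    def replace(self, **kw) -> "ActivitySeries":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# Export reading / writing
# ---------------------------------------------------------------------------

def read_activity_export(
    path,
    schema: Mapping[str, str] | None = None,
    distance_unit: str = "m",
) -> list[RawActivityRecord]:
    """Read a long-format activity export CSV into validated records.

    Parameters
    ----------
    path:
        CSV with (at least) the four columns named by ``schema``.
    schema:
        Map from canonical names (``patient_id,timestamp,metric,value``) to
        the file's column headers; defaults to identity.
    distance_unit:
        ``"m"`` or ``"km"``; kilometre distances are converted to metres.

    Malformed rows are collected and reported with their file line numbers
    (header = line 1) in a single :class:`ExportValidationError`; nothing is
    silently dropped.
    """
    if distance_unit not in ("m", "km"):
        raise ValueError("distance_unit must be 'm' or 'km'")
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for canon, col in colmap.items():
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} (for {canon})")

    pids_col = df[colmap["patient_id"]].to_list()
    ts_col = df[colmap["timestamp"]].to_list()
    metric_col = df[colmap["metric"]].to_list()
    value_col = df[colmap["value"]].to_list()

    records: list[RawActivityRecord] = []
    bad: list[tuple[int, str]] = []
    for i in range(len(df)):
        line = i + 2  # header is line 1
        pid = pids_col[i]
        raw_metric = str(metric_col[i]).strip().lower()
        metric = METRIC_ALIASES.get(raw_metric)
        if metric is None:
            bad.append((line, f"unknown metric {raw_metric!r}"))
            continue
        try:
            ts = datetime.fromisoformat(str(ts_col[i]).strip())
        except ValueError:
            bad.append((line, "unparseable timestamp"))
            continue
        try:
            value = float(value_col[i])
        except ValueError:
            bad.append((line, "non-numeric value"))
            continue
        if not np.isfinite(value) or value < 0:
            bad.append((line, f"invalid (negative or non-finite) value {value}"))
            continue
        if metric == "distance_m" and (
            distance_unit == "km" or raw_metric == "distance_km"
        ):
            value *= 1000.0
        records.append(RawActivityRecord(str(pid), ts, metric, value))
    if bad:
        raise ExportValidationError(bad)
    return records


def write_activity_export(records: Iterable[RawActivityRecord], path) -> None:
    """Write records back to the default long CSV layout (round-trip safe)."""
    rows = [
        {
            "patient_id": r.patient_id,
            "timestamp": r.timestamp.isoformat(),
            "metric": r.metric,
            "value": r.value,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(DEFAULT_SCHEMA)).to_csv(path, index=False)


def read_cohort_metadata(path) -> dict[str, PatientProfile]:
    """Read the cohort metadata CSV into a patient_id -> profile map."""
    df = pd.read_csv(path, dtype=str)
    required = ["patient_id", "surgery_date", "age", "bmi", "cci", "procedure"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"metadata missing required column {col!r}")
    profiles: dict[str, PatientProfile] = {}
    for _, row in df.iterrows():
        pid = str(row["patient_id"])
        if pid in profiles:
            raise DuplicateDayError(f"duplicate metadata row for patient {pid!r}")
        profiles[pid] = PatientProfile(
            patient_id=pid,
            surgery_date=date.fromisoformat(row["surgery_date"]),
            age=float(row["age"]),
            bmi=float(row["bmi"]),
            cci=int(row["cci"]),
            procedure=str(row["procedure"]),
        )
    return profiles


# ---------------------------------------------------------------------------
# Aggregation and alignment
# ---------------------------------------------------------------------------

def aggregate_to_daily(records: Sequence[RawActivityRecord]) -> ActivitySeries:
    """Sum hourly records to calendar-day totals for one patient and metric.

    Dates with no records are absent (missing), not zero.
    """
    if not records:
        raise MixedSeriesError("no records to aggregate")
    pids = {r.patient_id for r in records}
    metrics = {r.metric for r in records}
    if len(pids) > 1:
        raise MixedSeriesError(f"records span multiple patients: {sorted(pids)}")
    if len(metrics) > 1:
        raise MixedSeriesError(f"records span multiple metrics: {sorted(metrics)}")
    frame = pd.DataFrame(
        {
            "date": [pd.Timestamp(r.timestamp.date()) for r in records],
            "value": [r.value for r in records],
        }
    )
    daily = frame.groupby("date")["value"].sum().astype(float)
    daily.index = pd.DatetimeIndex(daily.index)
    return ActivitySeries(pids.pop(), metrics.pop(), daily)


def align_to_surgery(series: ActivitySeries, surgery_date: date) -> ActivitySeries:
    """Re-key a calendar series to integer day offsets from surgery.

    The surgery date maps to offset 0, the day before to -1, the day after
    to +1.  An empty series aligns to an empty series.
    """
    if series.data.empty:
        empty = pd.Series(dtype=float, index=pd.Index([], dtype=int))
        return ActivitySeries(
            series.patient_id, series.metric, empty, surgery_date=surgery_date
        )
    if series.is_aligned:
        raise ValueError("series is already aligned to surgery")
    anchor = pd.Timestamp(surgery_date)
    offsets = (pd.DatetimeIndex(series.data.index).normalize() - anchor).days
    aligned = pd.Series(
        series.data.to_numpy(dtype=float), index=offsets.astype(int)
    )
    return ActivitySeries(
        series.patient_id, series.metric, aligned, surgery_date=surgery_date
    )


# ---------------------------------------------------------------------------
# Canonical aligned-series CSV
# ---------------------------------------------------------------------------

def write_aligned_csv(series_list: Iterable[ActivitySeries], path) -> None:
    """Write aligned series to the canonical CSV (observed days only)."""
    rows = []
    for s in series_list:
        if not s.is_aligned:
            raise ValueError(f"series for {s.patient_id!r} is not aligned")
        for off, val in s.observed().items():
            rows.append(
                {
                    "patient_id": s.patient_id,
                    "day_offset": int(off),
                    "metric": s.metric,
                    "value": float(val),
                }
            )
    pd.DataFrame(
        rows, columns=["patient_id", "day_offset", "metric", "value"]
    ).to_csv(path, index=False)


def read_aligned_csv(path) -> dict[tuple[str, str], ActivitySeries]:
    """Read the canonical aligned-series CSV.

    Returns a ``(patient_id, metric) -> ActivitySeries`` map.  Duplicate
    (patient, day, metric) rows indicate a corrupt export and raise.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    for col in ("patient_id", "day_offset", "metric", "value"):
        if col not in df.columns:
            raise SchemaError(f"aligned CSV missing column {col!r}")
    out: dict[tuple[str, str], ActivitySeries] = {}
    for (pid, metric), grp in df.groupby(["patient_id", "metric"], sort=True):
        if grp["day_offset"].duplicated().any():
            raise DuplicateDayError(
                f"duplicate (day_offset) rows for patient {pid!r}, {metric}"
            )
        s = pd.Series(
            grp["value"].to_numpy(dtype=float),
            index=grp["day_offset"].to_numpy(dtype=int),
        )
        out[(str(pid), str(metric))] = ActivitySeries(str(pid), str(metric), s)
    return out


def write_cohort_metadata(profiles: Iterable[PatientProfile], path) -> None:
    rows = [
        {
            "patient_id": p.patient_id,
            "surgery_date": p.surgery_date.isoformat(),
            "age": p.age,
            "bmi": p.bmi,
            "cci": p.cci,
            "procedure": p.procedure,
        }
        for p in profiles
    ]
    pd.DataFrame(
        rows,
        columns=["patient_id", "surgery_date", "age", "bmi", "cci", "procedure"],
    ).to_csv(path, index=False)
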