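"""End-to-end orchestration: io -> preprocessing -> segmentation -> metrics.

``process_patient`` runs one aligned series through the full chain and
either returns a :class:`PatientResult` or raises :class:`PatientExcluded`
with a machine-readable reason code.  ``run_pipeline`` maps the chain over
a cohort, writes every artifact (processed series, QC reports,
segmentations, metrics, optional prediction evaluation) and a
:class:`RunManifest` that accounts for every patient in or out.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .errors import (
    InsufficientBaselineError,
    DegenerateBaselineError,
    MetricsError,
    ModelingError,
    PeriostepError,
    PipelineError,
    SegmentationError,
)
from .io import (
    ActivitySeries,
    PatientProfile,
    read_aligned_csv,
    read_cohort_metadata,
    write_aligned_csv,
)
from .metrics import RecoveryMetrics, compute_metrics, metrics_frame
from .prediction import (
    DeclineLabel,
    ExclusionRecord,
    evaluate_model,
    extract_features,
    feature_table,
)
from .preprocessing import (
    BaselineStats,
    NormalizedSeries,
    QCReport,
    check_eligibility,
    compute_baseline,
    normalize,
    qc_block_filter,
    select_window,
    smooth,
)
from .segmentation import EpochSegmentation, segment_epochs

try:
    __version__ = version("periostep")
except PackageNotFoundError:  # pragma: no cover - running from a checkout
    __version__ = "0+unknown"


class PatientExcluded(PeriostepError):
    """A patient dropped by a QC/eligibility rule, with the reason code."""

    def __init__(self, patient_id: str, reason: str):
        self.patient_id = patient_id
        self.reason = reason
        super().__init__(f"{patient_id}: {reason}")


@dataclass
class PatientResult:
    """Everything the pipeline computed for one analyzed patient."""

    series: ActivitySeries  # windowed + QC-filtered raw series
    raw_smoothed: ActivitySeries
    norm_smoothed: NormalizedSeries
    baseline: BaselineStats
    qc: QCReport
    segmentation: EpochSegmentation
    metrics: RecoveryMetrics


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    seed: int
    software_version: str
    input_digests: dict = field(default_factory=dict)
    patients_in: int = 0
    patients_analyzed: int = 0
    excluded: dict = field(default_factory=dict)  # reason -> count
    excluded_patients: list = field(default_factory=list)  # (id, reason)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seed": self.seed,
            "software_version": self.software_version,
            "input_digests": self.input_digests,
            "patients_in": self.patients_in,
            "patients_analyzed": self.patients_analyzed,
            "excluded": self.excluded,
            "excluded_patients": [list(x) for x in self.excluded_patients],
        }


def process_patient(
    series: ActivitySeries, config: PipelineConfig
) -> PatientResult:
    """Run one aligned series through window -> QC -> normalize -> smooth ->
    segment -> metrics.  Raises :class:`PatientExcluded` with a reason code
    at the first failed rule."""
    pid = series.patient_id
    windowed = select_window(series, config)
    elig = check_eligibility(windowed, config)
    if not elig.eligible:
        raise PatientExcluded(pid, elig.reasons[0])
    filtered, qc = qc_block_filter(windowed, config)
    qc.eligible = True
    if config.zero_is_missing_for_analysis:
        # recorded zeros are phone-non-carry artifacts, not immobility
        masked = filtered.data.mask(filtered.data == 0)
        filtered = filtered.replace(data=masked)
    try:
        baseline = compute_baseline(filtered, config)
        norm = normalize(filtered, baseline)
    except InsufficientBaselineError:
        raise PatientExcluded(pid, "insufficient_baseline")
    except DegenerateBaselineError:
        raise PatientExcluded(pid, "degenerate_baseline")
    norm_smoothed = smooth(norm, config)
    raw_smoothed = smooth(filtered, config)
    try:
        seg = segment_epochs(norm_smoothed, config)
        met = compute_metrics(raw_smoothed, norm_smoothed, baseline, seg)
    except (SegmentationError, MetricsError) as err:
        raise PatientExcluded(pid, err.reason)
    return PatientResult(
        series=filtered,
        raw_smoothed=raw_smoothed,
        norm_smoothed=norm_smoothed,
        baseline=baseline,
        qc=qc,
        segmentation=seg,
        metrics=met,
    )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    activity_paths: list,
    metadata_path,
    config: PipelineConfig | None = None,
    output_dir="periostep_out",
    metric: str = "steps",
    seed: int = 0,
    predict: bool = False,
    model_kind: str = "random_forest",
) -> RunManifest:
    """Execute the full cohort pipeline and write all artifacts.

    ``activity_paths`` are aligned-series CSVs (see :mod:`periostep.io`);
    ``metadata_path`` is the cohort metadata CSV.  Outputs under
    ``output_dir``: ``processed_series.csv`` (raw + smoothed + z columns),
    ``qc_reports.json``, ``segmentation.json``, ``metrics.csv``,
    ``manifest.json`` and, with ``predict=True``, ``features.csv`` +
    ``evaluation.json`` (labels = detected secondary decline).
    """
    config = config or PipelineConfig()
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    profiles = read_cohort_metadata(metadata_path)
    series_map: dict[str, ActivitySeries] = {}
    for path in activity_paths:
        for (pid, m), s in read_aligned_csv(path).items():
            if m != metric:
                continue
            if pid in series_map:
                raise PipelineError(f"patient {pid!r} appears in multiple inputs")
            series_map[pid] = s
    if not series_map:
        raise PipelineError("no_patients")

    manifest = RunManifest(
        config=config.snapshot(),
        seed=seed,
        software_version=__version__,
        input_digests={
            str(p): _sha256(p) for p in list(activity_paths) + [metadata_path]
        },
        patients_in=len(series_map),
    )

    results: dict[str, PatientResult] = {}
    qc_reports = {}
    for pid in sorted(series_map):
        try:
            res = process_patient(series_map[pid], config)
        except PatientExcluded as exc:
            manifest.excluded[exc.reason] = manifest.excluded.get(exc.reason, 0) + 1
            manifest.excluded_patients.append((pid, exc.reason))
            continue
        results[pid] = res
        qc_reports[pid] = res.qc.to_dict()
    manifest.patients_analyzed = len(results)

    # artifacts
    rows = []
    for pid, res in results.items():
        df = pd.DataFrame(
            {
                "patient_id": pid,
                "day_offset": res.series.data.index,
                "metric": metric,
                "value": res.series.data.to_numpy(),
                "smoothed": res.raw_smoothed.data.to_numpy(),
                "z_smoothed": res.norm_smoothed.data.to_numpy(),
            }
        )
        rows.append(df.dropna(subset=["value", "smoothed", "z_smoothed"], how="all"))
    if rows:
        pd.concat(rows, ignore_index=True).to_csv(
            out / "processed_series.csv", index=False
        )
    with open(out / "qc_reports.json", "w") as fh:
        json.dump(qc_reports, fh, indent=1)
    with open(out / "segmentation.json", "w") as fh:
        json.dump(
            {pid: res.segmentation.to_dict() for pid, res in results.items()},
            fh,
            indent=1,
        )
    if results:
        metrics_frame([res.metrics for res in results.values()]).to_csv(
            out / "metrics.csv", index=False
        )

    if predict and results:
        vectors, exclusions, labels = [], [], []
        for pid, res in results.items():
            profile = profiles.get(pid)
            if profile is None:
                exclusions.append(ExclusionRecord(pid, "no_metadata"))
                continue
            fv = extract_features(res.segmentation, res.metrics, profile)
            if isinstance(fv, ExclusionRecord):
                exclusions.append(fv)
                continue
            vectors.append(fv)
            labels.append(
                DeclineLabel(pid, res.segmentation.secondary_decline_present)
            )
        if vectors:
            feature_table(vectors).to_csv(out / "features.csv", index=False)
        try:
            report = evaluate_model(model_kind, vectors, labels, seed=seed)
            payload = report.to_dict()
        except ModelingError as err:
            payload = {"error": str(err)}
        payload["feature_exclusions"] = [
            {"patient_id": e.patient_id, "reason": e.reason} for e in exclusions
        ]
        with open(out / "evaluation.json", "w") as fh:
            json.dump(payload, fh, indent=1)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=1)
    return manifest
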