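"""Supervised prediction of secondary decline after initial recovery.

Trajectory features (recovery duration and slope, total improvement,
proportion of post-operative days above baseline) are combined with
clinical covariates (age, BMI, Charlson Comorbidity Index) to predict
whether a patient declines after recovering.  Models: logistic regression,
random forest, and generic gradient-boosted trees.  Evaluation is
stratified k-fold cross-validation with feature standardization fitted on
training folds only (an sklearn Pipeline, so no leakage), reporting both
accuracy and AUROC — accuracy alone is prevalence-sensitive.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .errors import FeatureExtractionError, ModelingError
from .io import PatientProfile
from .metrics import RecoveryMetrics
from .segmentation import EpochSegmentation

FEATURE_NAMES = (
    "recovery_duration_days",
    "recovery_slope",
    "total_improvement_z",
    "proportion_above_baseline",
    "age",
    "bmi",
    "cci",
)

MODEL_KINDS = ("logistic_regression", "random_forest", "gradient_boosting")


@dataclass(frozen=True)
class FeatureVector:
    """Assembled per-patient predictors (no missing entries by contract)."""

    patient_id: str
    recovery_duration_days: float
    recovery_slope: float
    total_improvement_z: float
    proportion_above_baseline: float
    age: float
    bmi: float
    cci: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FEATURE_NAMES], dtype=float)


@dataclass(frozen=True)
class DeclineLabel:
    patient_id: str
    declined: bool


@dataclass(frozen=True)
class ExclusionRecord:
    """A patient dropped from the feature table, with the reason."""

    patient_id: str
    reason: str


def extract_features(
    seg: EpochSegmentation,
    metrics: RecoveryMetrics,
    profile: PatientProfile,
) -> FeatureVector | ExclusionRecord:
    """Deterministically assemble one feature vector.

    Patients without an immediate-postoperative-recovery epoch cannot
    contribute recovery features and are returned as an
    :class:`ExclusionRecord` rather than silently dropped.  Missing
    clinical covariates raise.
    """
    missing = [
        f for f in ("age", "bmi", "cci") if getattr(profile, f, None) is None
    ]
    if missing:
        raise FeatureExtractionError(
            f"patient {profile.patient_id!r} missing covariates: {missing}"
        )
    rec = seg.get("immediate_postoperative_recovery")
    if rec is None:
        return ExclusionRecord(profile.patient_id, "no_recovery_epoch")
    if rec.slope is None:
        return ExclusionRecord(profile.patient_id, "recovery_slope_undefined")
    return FeatureVector(
        patient_id=profile.patient_id,
        recovery_duration_days=float(rec.duration_days),
        recovery_slope=float(rec.slope),
        total_improvement_z=float(metrics.total_improvement_z),
        proportion_above_baseline=float(metrics.proportion_above_baseline),
        age=float(profile.age),
        bmi=float(profile.bmi),
        cci=float(profile.cci),
    )


def feature_table(vectors: list[FeatureVector]) -> pd.DataFrame:
    df = pd.DataFrame([v.as_array() for v in vectors], columns=list(FEATURE_NAMES))
    df.insert(0, "patient_id", [v.patient_id for v in vectors])
    return df


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

def _make_estimator(model_kind: str, seed: int) -> Pipeline:
    if model_kind == "logistic_regression":
        clf = LogisticRegression(max_iter=2000, random_state=seed)
    elif model_kind == "random_forest":
        clf = RandomForestClassifier(n_estimators=200, random_state=seed)
    elif model_kind == "gradient_boosting":
        clf = GradientBoostingClassifier(
            n_estimators=100, max_depth=3, random_state=seed
        )
    else:
        raise ValueError(f"unknown model kind {model_kind!r}; use {MODEL_KINDS}")
    # scaler inside the pipeline => fitted on training folds only during CV
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _design(
    features: list[FeatureVector], labels: list[DeclineLabel]
) -> tuple[np.ndarray, np.ndarray]:
    label_map = {l.patient_id: bool(l.declined) for l in labels}
    missing = [v.patient_id for v in features if v.patient_id not in label_map]
    if missing:
        raise ModelingError(f"no label for patients: {missing[:5]}")
    X = np.vstack([v.as_array() for v in features])
    y = np.array([label_map[v.patient_id] for v in features], dtype=int)
    return X, y


def fit_decline_model(
    features: list[FeatureVector],
    labels: list[DeclineLabel],
    model_kind: str = "random_forest",
    seed: int = 0,
) -> Pipeline:
    """Fit a decline classifier on the full feature table (seeded)."""
    X, y = _design(features, labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ModelingError("labels contain a single class; cannot fit")
    if counts.min() < 10:
        raise ModelingError(
            f"need >= 10 patients per class (got {dict(zip(classes, counts))})"
        )
    est = _make_estimator(model_kind, seed)
    est.fit(X, y)
    return est


@dataclass
class EvaluationReport:
    """Stratified k-fold CV results; never evaluated on training folds."""

    model_kind: str
    k_folds: int
    seed: int
    n: int
    prevalence: float
    fold_accuracy: list[float] = field(default_factory=list)
    fold_auroc: list[float | None] = field(default_factory=list)

    @property
    def accuracy_mean(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def accuracy_sd(self) -> float:
        return float(np.std(self.fold_accuracy, ddof=1)) if len(
            self.fold_accuracy
        ) > 1 else 0.0

    @property
    def auroc_mean(self) -> float | None:
        vals = [a for a in self.fold_auroc if a is not None]
        return float(np.mean(vals)) if vals else None

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "k_folds": self.k_folds,
            "seed": self.seed,
            "n": self.n,
            "prevalence": self.prevalence,
            "fold_accuracy": self.fold_accuracy,
            "fold_auroc": self.fold_auroc,
            "accuracy_mean": self.accuracy_mean,
            "accuracy_sd": self.accuracy_sd,
            "auroc_mean": self.auroc_mean,
        }


def evaluate_model(
    model_kind: str,
    features: list[FeatureVector],
    labels: list[DeclineLabel],
    k_folds: int = 5,
    seed: int = 0,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of a decline classifier.

    Each fold refits the whole pipeline (scaler included) on its training
    part.  AUROC is None for a fold whose test part is single-class (only
    possible when k approaches n).
    """
    X, y = _design(features, labels)
    if k_folds < 2:
        raise ModelingError("k_folds must be >= 2")
    if len(np.unique(y)) < 2:
        raise ModelingError("labels contain a single class; cannot evaluate")
    if k_folds > min(np.bincount(y)) and k_folds != len(y):
        k_folds = int(max(2, min(np.bincount(y))))
    if k_folds == len(y):  # leave-one-out degenerates to unstratified
        splits = [([j for j in range(len(y)) if j != i], [i]) for i in range(len(y))]
    else:
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
        splits = list(skf.split(X, y))
    report = EvaluationReport(
        model_kind=model_kind,
        k_folds=k_folds,
        seed=seed,
        n=len(y),
        prevalence=float(y.mean()),
    )
    for train, test in splits:
        est = _make_estimator(model_kind, seed)
        est.fit(X[train], y[train])
        pred = est.predict(X[test])
        report.fold_accuracy.append(float(accuracy_score(y[test], pred)))
        if len(np.unique(y[test])) == 2:
            proba = est.predict_proba(X[test])[:, 1]
            report.fold_auroc.append(float(roc_auc_score(y[test], proba)))
        else:
            report.fold_auroc.append(None)
    return report
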