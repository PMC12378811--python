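"""Predict secondary decline from trajectory and clinical features.

A 200-patient cohort is simulated with decline risk rising in recovery
duration (logistic effect, standardized beta 2.5).  Features extracted by
the pipeline (recovery duration/slope, improvement, proportion above
baseline) plus age, BMI and Charlson index feed a random forest evaluated
with stratified 5-fold cross-validation.
"""
from periostep import (
    DeclineLabel,
    FeatureVector,
    PipelineConfig,
    evaluate_model,
    extract_features,
    process_patient,
    simulate_cohort,
)
from periostep.pipeline import PatientExcluded

config = PipelineConfig()
cohort = simulate_cohort(
    200, seed=11, decline_prevalence=0.35,
    effect_spec={"recovery_duration_days": 2.5},
)

vectors, labels = [], []
for series, truth, profile in zip(cohort.series, cohort.truths, cohort.profiles):
    try:
        res = process_patient(series, config)
    except PatientExcluded:
        continue
    fv = extract_features(res.segmentation, res.metrics, profile)
    if isinstance(fv, FeatureVector):
        vectors.append(fv)
        labels.append(DeclineLabel(profile.patient_id, truth.declined))

for kind in ("logistic_regression", "random_forest", "gradient_boosting"):
    rep = evaluate_model(kind, vectors, labels, k_folds=5, seed=11)
    print(
        f"{kind:22s} accuracy {rep.accuracy_mean:.3f} ± {rep.accuracy_sd:.3f}  "
        f"AUROC {rep.auroc_mean:.3f}  (n={rep.n}, prevalence {rep.prevalence:.2f})"
    )
# Accuracy well above the majority-class rate plus AUROC ~0.9 shows the
# planted duration effect is recoverable from pipeline-derived features.
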