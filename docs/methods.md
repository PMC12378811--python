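# Methods

This note documents the model behind `periostep`, the defaults and why
they were chosen, what the simulator does and does not emulate, and the
numerical decisions a maintainer would want recorded. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Data model and alignment

Activity arrives as long-format exports — one row per
`(patient, timestamp, metric, value)` with metrics `steps`, `distance_m`,
`flights` — typically hourly buckets from a phone health API. Timestamps
are taken as local wall-clock time and aggregated by local calendar date
(phone health databases report daily totals in local time; the pipeline
never needs timezone arithmetic). Distance is stored in meters; the
reader converts kilometre exports (`distance_unit="km"` or a
`distance_km` metric label). Daily totals are re-keyed as integer offsets
from the surgery date: day 0 is surgery, negative is pre-operative.

A calendar date with no records is *missing*, never zero. A recorded zero
is kept as a true zero at the I/O layer; its interpretation is a
downstream policy (below). Duplicate `(patient, day, metric)` rows in a
daily export indicate corruption and raise rather than merge.

## Perioperative window and eligibility

Defaults: 365 days each side, surgery day excluded, so a complete patient
contributes exactly 730 daily slots. Day 0 is excluded because
in-hospital phone carry makes it uninterpretable. Eligibility requires
the earliest observed pre-operative day to reach −365 and the latest
post-operative day to reach +365, with zero tolerance — the
one-year-each-side inclusion rule taken literally. With realistic
missingness a noticeable fraction of patients fail this screen; that is
the rule working, not a defect, and the run manifest accounts for every
exclusion by reason.

## Patient-month QC

The window is partitioned into consecutive 30-day blocks anchored at
surgery (pre-op: [−30,−1], [−60,−31], …; post-op: [+1,+30], …; the far
edge block is clipped). Anchoring at surgery rather than at calendar
months keeps blocks comparable across patients regardless of surgery
date. A block whose fraction of missing-or-zero days is **strictly**
greater than 0.20 (the literal reading of "more than 20%") has all its
days set to missing. Nothing is imputed.

**Zero-activity days.** Zeros count toward the 20% exclusion fraction
(`zero_is_missing_for_qc`, default on). In addition, retained zeros are
masked to missing before normalization and smoothing
(`zero_is_missing_for_analysis`, default on). Rationale: a passively
recorded zero is indistinguishable from the phone being left at home, and
a single such day inside a 14-day window depresses the smoothed curve by
roughly `baseline_mean / (14·σ)` ≈ 0.36 SD at the default noise level —
two of them can exceed the 0.5 SD decline threshold and fake a sustained
secondary decline. Measured on simulated non-decliners, masking removes
essentially all such false positives. Disabling the flag restains zeros
as true zeros for every downstream statistic.

## Baseline normalization

The baseline window defaults to [−365, −91]: the reference level must
exclude the acute pre-operative decline phase, or normalization absorbs
the decline it is supposed to expose. The 90-day cut is this package's
choice and is configurable; both the decline-free sub-window and the full
pre-operative year are supported. Baseline statistics are the mean and
*sample* SD (n−1) of observed baseline days; fewer than 2 observed days
is an error, and SD = 0 makes normalization undefined (degenerate-baseline
error at `normalize`). By construction the baseline window of a
normalized series has mean 0 and SD 1 to machine precision — a tested
invariant.

## Smoothing

Centered 14-day moving average: the window for day *t* is [t−7, t+6].
Centered rather than trailing because a trailing mean lags the signal by
half a window and would bias every epoch boundary late; the choice is
switchable (`smoothing_centered`). Missing days are excluded from each
window mean; a window with no observed day yields missing; edges use the
truncated window. The smoother is evaluated on a contiguous daily grid, so
true gaps (the excluded surgery day, QC-dropped blocks) count as missing
inside windows rather than being skipped over. Smoothed values exist on
any day whose window contains an observed day — smoothing interpolates
across short gaps by design; only fully-missing windows stay missing.
Because normalization is affine and the moving average linear, the two
commute: the raw-scale smoothed curve is recovered exactly as
`μ + σ·z_smoothed`, which the full-recovery criterion relies on. A 7-day
weekday/weekend rhythm integrates to ~0 over the 14-day window — a tested
property, and the reason 14 is a good default for step data.

## Epoch segmentation

Segmentation operates on the smoothed z trajectory (consistent with
thresholds "measured in standard deviations"; whether the original
analyses segmented z-scores or raw counts is not stated — this is our
documented reading). The published methodology does not state its SD
thresholds; the defaults here are **0.5 SD** sustained **≥14 days** for
declines — the single largest open parameter, configurable and echoed in
every output — and **≥28 consecutive days** (twice the smoothing window,
so no single-window artifact can qualify) for "sustained" full recovery.

Rules, in scan order:

1. *Preoperative baseline*: the observed span of the baseline window.
2. *Acute preoperative decline*: the longest run of consecutive days in
   [−90, −1] with z ≤ −0.5, if ≥14 days (ties broken to the earliest run).
3. *Post-operative nadir*: minimum smoothed z in [+1, +90], ties to the
   earliest day. A recovery epoch is emitted only when the nadir itself
   sits at or below −0.5 SD — otherwise there is nothing to recover from,
   and a flat trajectory yields only the baseline epoch.
4. *Immediate postoperative recovery*: from the nadir to the day before
   full-recovery onset. When full recovery is never met, "the climb
   ends" is operationalized as a running-maximum stall: the epoch ends at
   the last day a new running maximum was set before the first stretch of
   more than 14 days without one. This is deterministic and robust to
   plateau noise, unlike a pointwise slope-sign test.
5. *Full recovery*: first run of ≥28 consecutive observed days with
   raw-scale smoothed activity ≥ 1.8 × baseline mean (the literal reading
   of "80% improvement above baseline"; the alternative reading — closing
   80% of the nadir-to-baseline gap — is selectable via
   `recovery_mode="fraction_of_nadir_gap"`). Because the criterion is a
   ratio to the patient's own baseline, the call is invariant to
   rescaling the raw counts — a tested property.
6. *Secondary decline*: after full-recovery onset, the first ≥14-day run
   with z at least 0.5 SD below the recovery reference level. The
   reference is the mean z over the *first 28 days* of the full-recovery
   epoch rather than the whole epoch: using the whole epoch is circular
   (a large decline drags its own reference down). The full-recovery
   epoch is then truncated at the decline start. Whether a secondary
   decline may follow a recovery that never met the full criterion is
   configurable (`secondary_decline_requires_full_recovery`, default
   true).

Epoch statistics: duration (inclusive), mean z, least-squares slope over
observed (day, z) pairs (flagged undefined with <2 observations), and
magnitude (mean z minus baseline-epoch mean z). Epochs are emitted in
canonical order, at most one per label, non-overlapping.

## Continuous recovery metrics

The epoch-free view treats the post-operative record as a stream:
proportion of observed post-op days with smoothed raw activity strictly
above the baseline mean (exceedance is judged on the smoothed series —
raw daily counts are noise-dominated; the comparison point is the
baseline *mean*, a percentile variant being a possible extension); first
day at or above baseline; mean post-op z minus mean pre-op z; net SD·days
(`auc_z`, one day per observation); and the recovery-epoch duration.
Cohort comparisons default to Mann–Whitney U (small cohorts, skewed
durations) with Welch's t available; `cohort_report` applies
Benjamini–Hochberg across the requested metrics and discloses it in the
output. No correction is applied inside a single comparison.

## Decline prediction

Features: recovery duration and slope, total improvement, proportion
above baseline ("activity trends" is not precisely defined upstream; the
slope and the exceedance proportion are our reading), plus age, BMI, CCI.
Patients without a recovery epoch are excluded with a logged reason, not
silently dropped. Models: logistic regression, random forest (200
trees), and gradient-boosted trees (100 trees, depth 3) as the generic
boosted-tree family. Evaluation is stratified 5-fold cross-validation
(no protocol is published; 5-fold is the conventional default), with the
standardizer inside the per-fold pipeline so no statistic leaks from test
folds. Accuracy **and** AUROC are both reported: accuracy alone is
prevalence-sensitive. All fits are seeded; identical seeds reproduce
identical reports.

## The simulator

`simulate_patient` draws a piecewise-linear mean curve through
(decline start, baseline) → (0⁻, baseline·(1−depth)) →
(nadir day, baseline·nadir level) → (recovery end, baseline·plateau),
constant outside, with an optional secondary decline ramping down over 14
days. On top: Gaussian daily noise truncated at zero (simpler than a
lognormal and adequate for exercising the pipeline; the truncation bias
is negligible at the default noise level), a sinusoidal weekday/weekend
rhythm, i.i.d. Bernoulli missingness (a burst mode with geometric run
lengths exercises the patient-month rule), and Bernoulli zero days.

Cohort defaults, chosen once as the study conditions the pipeline should
face: baseline mean uniform on 4,000–12,000 steps/day (the
sedentary-to-active range); daily noise SD 20% of the baseline mean;
weekly amplitude 10%; pre-operative decline of 25–40% starting 45–75 days
out; nadir at 30–55% of baseline 7–21 days post-op; recovery ramp ending
80–200 days post-op; 80% of patients plateau at 1.9–2.3× baseline
(responders, comfortably beyond the 1.8× criterion) and 20% at 1.1–1.5×;
missing rate 5%, zero rate 2%. Decline labels are drawn from a logistic
model on standardized planted features with the intercept calibrated to
the requested prevalence; labeled decliners get a 0.6–0.9×baseline drop
planted 45+ days after recovery ends.

`GroundTruth.expected_boundaries` converts planted parameters into the
day each detection rule *should* fire — threshold crossings computed in
closed form on the mean curve, using the scenario's effective noise SD
(√(σ² + A²/2), since normalization sees noise plus rhythm). Detection is
scored against these crossings, not against the ramp kinks: a decline
epoch begins where the trajectory crosses −0.5 SD, which is days later
than where the planted ramp starts.

**What the simulator does not emulate:** heavy-tailed daily counts,
seasonal and weather effects, behavior change from illness unrelated to
surgery, device switches, enrollment-driven censoring, or any coupling
between missingness and activity level (sick patients may carry the phone
less — missingness here is ignorable by construction). Passing tests
demonstrate the pipeline recovers structure it was designed to detect
under these idealized conditions; they are not clinical validation, and
the published cohort-level figures (concordance with documentation,
fraction fully recovered, clinical prediction accuracy) are not
reproducible without patient data.

## Numerical and scale choices

Problem sizes used by the test suite and acceptance script — 200-patient
cohorts for detection and prediction, 50 per arm for the cohort contrast,
1,000 replicates for the normalization and smoothing oracles — are the
package's chosen defaults, large enough for stable rates while keeping a
full run in the tens of seconds. After self-normalization the daily z
noise is ~1 by construction regardless of the raw noise level, and the
14-day mean leaves ~0.27 SD on the smoothed trajectory; boundary accuracy
therefore depends only on the planted excursion sizes relative to daily
noise. Ties in the nadir search and in run selection break to the
earliest day for determinism. All randomness flows through
`numpy.random.default_rng` seeds; every reported quantity is bit-stable
under a fixed seed.

## Known limitations

- The SD thresholds (0.5 SD, 14-day runs, 28-day sustainment) are this
  package's documented defaults for parameters the methodology leaves
  unstated; conclusions can be sensitive to them, which is why every
  output embeds the config snapshot.
- Eligibility is all-or-nothing at exactly one year each side; patients
  a day short are excluded rather than analyzed with a shorter window.
- The maximal-run rule for the acute decline biases the detected onset
  late when noise fragments the sub-threshold run.
- `auc_z` sums observed days only; under heavy missingness it is not
  comparable across patients without normalizing by observed-day count.
- Distance and flights series flow through the same pipeline but all
  defaults were chosen with step counts in mind.
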