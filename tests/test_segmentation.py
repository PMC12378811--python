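"""Five-epoch segmentation, full-recovery call, and epoch statistics."""
import numpy as np
import pytest

from periostep import (
    BaselineStats,
    Epoch,
    PipelineConfig,
    classify_full_recovery,
    process_patient,
    quantify_epoch,
    segment_epochs,
    simulate_patient,
    SimScenario,
)
from periostep.errors import SegmentationError
from periostep.segmentation import EPOCH_LABELS

from conftest import make_normalized


def _z(raw, mean, sd):
    return (raw - mean) / sd


def plateau_series(plateau_value, plateau_days, mean=4000.0, sd=1000.0,
                   nadir_value=1500.0):
    """Deterministic z trajectory: flat baseline, dip to a nadir at day 10,
    ramp to ``plateau_value`` held for ``plateau_days``."""
    mapping = {}
    for t in range(-365, 0):
        mapping[t] = 0.0
    for t in range(1, 11):
        mapping[t] = _z(
            mean + (nadir_value - mean) * t / 10.0, mean, sd
        )
    ramp_end = 60
    for t in range(11, ramp_end):
        frac = (t - 10) / (ramp_end - 10)
        mapping[t] = _z(nadir_value + frac * (plateau_value - nadir_value), mean, sd)
    for t in range(ramp_end, ramp_end + plateau_days):
        mapping[t] = _z(plateau_value, mean, sd)
    return make_normalized(mapping, mean=mean, sd=sd)


class TestFullRecoveryCriterion:
    def test_sustained_plateau_at_1p8x_baseline_flags(self, config):
        ns = plateau_series(7500.0, 40)
        achieved, onset = classify_full_recovery(ns, ns.baseline, config)
        assert achieved
        # 7500 >= 1.8 * 4000 = 7200 first holds on the ramp
        raw = ns.baseline.mean + ns.baseline.sd * ns.data
        assert raw.loc[onset] >= 7200.0
        assert raw.loc[onset - 1] < 7200.0

    def test_exact_threshold_counts(self, config):
        ns = plateau_series(7200.0, 40)
        achieved, onset = classify_full_recovery(ns, ns.baseline, config)
        assert achieved

    def test_just_below_threshold_never_flags(self, config):
        ns = plateau_series(7200.0 - 1e-6, 300)
        achieved, _ = classify_full_recovery(ns, ns.baseline, config)
        assert not achieved

    def test_unsustained_plateau_not_flagged(self, config):
        # threshold held for sustained_days - 1 = 27 days only
        mapping = {t: 0.0 for t in range(-365, 0)}
        for t in range(1, 28):
            mapping[t] = _z(7500.0, 4000.0, 1000.0)
        mapping[28] = _z(3000.0, 4000.0, 1000.0)
        ns = make_normalized(mapping)
        achieved, _ = classify_full_recovery(ns, ns.baseline, config)
        assert not achieved

    def test_nadir_gap_mode_uses_gap_fraction(self):
        config = PipelineConfig(recovery_mode="fraction_of_nadir_gap")
        # nadir 1500, baseline 4000 -> threshold 1500 + 0.8*2500 = 3500
        ns = plateau_series(3600.0, 60)
        achieved, _ = classify_full_recovery(ns, ns.baseline, config)
        assert achieved
        default = PipelineConfig()
        achieved_default, _ = classify_full_recovery(ns, ns.baseline, default)
        assert not achieved_default  # 3600 << 7200

    def test_flag_invariant_to_raw_rescaling(self, config):
        # the criterion is a ratio to baseline mean, so steps -> steps * c
        # must not change the call
        scenario = SimScenario(seed=21, missing_rate=0.0, zero_rate=0.0)
        series, _ = simulate_patient(scenario)
        res = process_patient(series, config)
        scaled = series.replace(data=series.data * 2.5)
        res_scaled = process_patient(scaled, config)
        assert (
            res.segmentation.full_recovery_achieved
            == res_scaled.segmentation.full_recovery_achieved
        )


class TestSegmentEpochs:
    def test_flat_series_yields_only_baseline(self, config):
        rng = np.random.default_rng(0)
        mapping = {
            t: float(v)
            for t, v in zip(
                [t for t in range(-365, 366) if t != 0],
                rng.normal(0.0, 0.02, 730),
            )
        }
        seg = segment_epochs(make_normalized(mapping), config)
        assert [e.label for e in seg.epochs] == ["preoperative_baseline"]
        assert not seg.full_recovery_achieved
        assert not seg.secondary_decline_present

    def test_planted_boundaries_recovered_within_tolerance(self, config):
        scenario = SimScenario(
            seed=33,
            preop_decline_start=-60,
            nadir_offset=10,
            recovery_end_offset=120,
            missing_rate=0.02,
        )
        series, truth = simulate_patient(scenario)
        res = process_patient(series, config)
        seg = res.segmentation
        expected = truth.expected_boundaries(config)
        rec = seg.get("immediate_postoperative_recovery")
        assert rec is not None
        assert abs(rec.start_offset - expected["nadir"]) <= 10
        fr = seg.get("full_recovery")
        assert fr is not None
        assert abs(fr.start_offset - expected["recovery_onset"]) <= 10
        assert seg.get("acute_preoperative_decline") is not None

    def test_planted_secondary_decline_detected(self, config):
        scenario = SimScenario(seed=5, secondary_decline=(250, 0.8), missing_rate=0.0)
        series, _ = simulate_patient(scenario)
        res = process_patient(series, config)
        assert res.segmentation.secondary_decline_present
        sec = res.segmentation.get("secondary_decline")
        assert abs(sec.start_offset - 250) <= 21

    def test_no_postop_data_raises(self, config):
        mapping = {t: 0.1 for t in range(-365, 0)}
        with pytest.raises(SegmentationError, match="no_postop_data"):
            segment_epochs(make_normalized(mapping), config)

    def test_epochs_ordered_and_non_overlapping_on_random_cohort(self, config):
        from periostep import simulate_cohort

        cohort = simulate_cohort(40, seed=17, decline_prevalence=0.4)
        order = {label: i for i, label in enumerate(EPOCH_LABELS)}
        checked = 0
        for s in cohort.series:
            try:
                seg = process_patient(s, config).segmentation
            except Exception:
                continue
            checked += 1
            labels = [e.label for e in seg.epochs]
            assert labels == sorted(labels, key=order.__getitem__)
            assert len(labels) == len(set(labels))
            for a, b in zip(seg.epochs, seg.epochs[1:]):
                assert a.end_offset < b.start_offset
            assert seg.full_recovery_achieved == (seg.get("full_recovery") is not None)
            pre = [e for e in seg.epochs if e.label.startswith(("preoperative", "acute"))]
            assert all(e.end_offset <= -1 for e in pre)
            post = [e for e in seg.epochs if e not in pre]
            assert all(e.start_offset >= 1 for e in post)
        assert checked >= 30

    def test_decline_detection_monotone_in_threshold(self):
        # raising the SD threshold can only remove, never create, a decline
        for seed in range(12):
            scenario = SimScenario(seed=seed, preop_decline_depth=0.2)
            series, _ = simulate_patient(scenario)
            found = {}
            for thr in (0.3, 0.6, 0.9, 1.2):
                config = PipelineConfig(sd_change_threshold=thr)
                try:
                    seg = process_patient(series, config).segmentation
                except Exception:
                    continue
                found[thr] = seg.get("acute_preoperative_decline") is not None
            thresholds = sorted(found)
            for lo, hi in zip(thresholds, thresholds[1:]):
                assert found[hi] <= found[lo]


class TestQuantifyEpoch:
    def test_linear_epoch_recovers_slope(self):
        mapping = {t: 0.1 * (t - 20) for t in range(20, 40)}
        ns = make_normalized(mapping)
        ep = quantify_epoch(ns, Epoch("full_recovery", 20, 39))
        assert ep.slope == pytest.approx(0.1)
        assert ep.duration_days == 20

    def test_constant_epoch_zero_slope_and_magnitude(self):
        mapping = {t: 1.5 for t in range(1, 30)}
        ns = make_normalized(mapping)
        ep = quantify_epoch(ns, Epoch("full_recovery", 1, 29), baseline_mean_z=0.2)
        assert ep.slope == pytest.approx(0.0, abs=1e-12)
        assert ep.magnitude == pytest.approx(1.3)

    def test_single_day_epoch_flags_slope_undefined(self):
        ns = make_normalized({5: 0.7})
        ep = quantify_epoch(ns, Epoch("secondary_decline", 5, 5))
        assert ep.duration_days == 1
        assert not ep.slope_defined
        assert ep.slope is None
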