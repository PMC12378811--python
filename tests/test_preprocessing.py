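"""Window selection, eligibility, patient-month QC, normalization, smoothing."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from periostep import (
    BaselineStats,
    PipelineConfig,
    check_eligibility,
    compute_baseline,
    moving_average,
    normalize,
    qc_block_filter,
    select_window,
    smooth,
)
from periostep.errors import DegenerateBaselineError, InsufficientBaselineError
from periostep.preprocessing import _blocks

from conftest import complete_series, make_aligned


def brute_force_smooth(values, window):
    """Independent windowed-mean oracle (centered, missingness-aware)."""
    left = window // 2
    right = window - 1 - left
    n = len(values)
    out = []
    for t in range(n):
        vals = [
            values[j]
            for j in range(max(0, t - left), min(n, t + right + 1))
            if not math.isnan(values[j])
        ]
        out.append(sum(vals) / len(vals) if vals else math.nan)
    return out


class TestSelectWindow:
    def test_complete_two_year_series_has_730_slots(self, config):
        series = complete_series(config, lambda t: 4000.0)
        windowed = select_window(series, config)
        assert len(windowed.data) == 730
        assert windowed.n_observed == 730

    def test_day_zero_dropped(self, config):
        series = complete_series(config, lambda t: 4000.0)
        windowed = select_window(series, config)
        assert 0 not in windowed.data.index

    def test_far_out_series_yields_empty_observed(self, config):
        series = make_aligned({-450: 1.0, -420: 2.0})
        windowed = select_window(series, config)
        assert windowed.n_observed == 0
        assert len(windowed.data) == 730

    def test_slot_count_never_exceeds_window(self, config):
        series = make_aligned({-10: 1.0, 5: 2.0})
        windowed = select_window(series, config)
        assert len(windowed.data) == config.pre_window_days + config.post_window_days
        assert windowed.n_observed == 2


class TestEligibility:
    def _spanning(self, config, lo, hi):
        series = make_aligned({t: 4000.0 for t in range(lo, hi + 1) if t != 0})
        return check_eligibility(select_window(series, config), config)

    def test_full_span_is_eligible(self, config):
        assert self._spanning(config, -365, 365).eligible

    def test_short_preop_span_flagged(self, config):
        report = self._spanning(config, -100, 365)
        assert not report.eligible
        assert report.reasons == ["insufficient_preop_span"]

    def test_one_day_short_postop_is_ineligible(self, config):
        assert not self._spanning(config, -365, 364).eligible


class TestQCBlocks:
    def _series_with_missing(self, config, n_missing_in_first_block):
        mapping = {t: 4000.0 for t in range(-365, 366) if t != 0}
        for t in range(1, n_missing_in_first_block + 1):
            del mapping[t]
        return select_window(make_aligned(mapping), config)

    def test_seven_of_thirty_missing_drops_block(self, config):
        filtered, report = qc_block_filter(
            self._series_with_missing(config, 7), config
        )
        assert filtered.data.loc[1:30].isna().all()
        block = next(b for b in report.blocks if b.start_offset == 1)
        assert not block.kept
        assert block.missing_or_zero_fraction == pytest.approx(7 / 30)

    def test_six_of_thirty_missing_keeps_block(self, config):
        filtered, report = qc_block_filter(
            self._series_with_missing(config, 6), config
        )
        block = next(b for b in report.blocks if b.start_offset == 1)
        assert block.kept  # 6/30 = 0.20 is not strictly greater than 20%
        assert filtered.data.loc[7:30].notna().all()

    def test_zero_days_count_toward_exclusion(self, config):
        mapping = {t: 4000.0 for t in range(-365, 366) if t != 0}
        for t in range(1, 8):
            mapping[t] = 0.0
        filtered, _ = qc_block_filter(select_window(make_aligned(mapping), config), config)
        assert filtered.data.loc[1:30].isna().all()

    def test_complete_block_retained_untouched(self, config):
        series = select_window(complete_series(config, lambda t: 4000.0), config)
        filtered, report = qc_block_filter(series, config)
        assert all(b.kept for b in report.blocks)
        pd.testing.assert_series_equal(filtered.data, series.data)

    def test_partition_covers_window_exactly_once(self, config):
        days = []
        for start, end in _blocks(config):
            days.extend(range(start, end + 1))
        expected = [t for t in range(-365, 366) if t != 0]
        assert sorted(days) == expected
        assert len(days) == len(set(days))

    def test_passing_blocks_never_lose_days(self, config):
        rng = np.random.default_rng(5)
        mapping = {
            t: float(rng.integers(1, 9000))
            for t in range(-365, 366)
            if t != 0 and rng.random() > 0.1
        }
        series = select_window(make_aligned(mapping), config)
        filtered, report = qc_block_filter(series, config)
        for b in report.blocks:
            if b.kept:
                pd.testing.assert_series_equal(
                    filtered.data.loc[b.start_offset : b.end_offset],
                    series.data.loc[b.start_offset : b.end_offset],
                )


class TestBaselineAndNormalize:
    def test_two_value_baseline_hand_computation(self, config):
        mapping = {-300: 3000.0, -200: 5000.0}
        stats = compute_baseline(make_aligned(mapping), config)
        assert stats.mean == pytest.approx(4000.0)
        assert stats.sd == pytest.approx(math.sqrt(2) * 1000, rel=1e-12)  # n-1
        assert stats.n_days == 2

    def test_empty_baseline_window_raises(self, config):
        with pytest.raises(InsufficientBaselineError):
            compute_baseline(make_aligned({-10: 1.0, 5: 2.0}), config)

    def test_constant_baseline_degenerates_on_normalize(self, config):
        series = make_aligned({t: 4000.0 for t in range(-365, -90)})
        stats = compute_baseline(series, config)
        assert stats.sd == 0.0
        with pytest.raises(DegenerateBaselineError):
            normalize(series, stats)

    def test_z_scores_reflect_individual_baselines(self):
        # +1000 steps means z=1 for a sedentary patient with sd 1000 but
        # only z=1/3 when the individual's day-to-day sd is 3000
        series = make_aligned({-100: 5000.0})
        z1 = normalize(series, BaselineStats(4000.0, 1000.0, 50)).data.loc[-100]
        assert z1 == pytest.approx(1.0)
        active = make_aligned({-100: 13000.0})
        z2 = normalize(active, BaselineStats(12000.0, 1000.0, 50)).data.loc[-100]
        assert z2 == pytest.approx(1.0)
        z3 = normalize(active, BaselineStats(12000.0, 3000.0, 50)).data.loc[-100]
        assert z3 == pytest.approx(1.0 / 3.0)

    def test_value_at_mean_maps_to_zero(self):
        z = normalize(make_aligned({-5: 4000.0}), BaselineStats(4000.0, 500.0, 30))
        assert z.data.loc[-5] == 0.0

    def test_missing_days_stay_missing(self, config):
        mapping = {t: 4000.0 + 10 * t for t in range(-365, -90)}
        series = select_window(make_aligned(mapping), config)
        norm = normalize(series, compute_baseline(series, config))
        assert norm.data.loc[1:].isna().all()

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_normalization_identity_property(self, seed):
        # after compute_baseline + normalize, the baseline window has
        # mean 0 and sample sd 1 to machine precision
        config = PipelineConfig()
        rng = np.random.default_rng(seed)
        mapping = {
            t: float(v)
            for t, v in zip(
                range(-365, -90), rng.gamma(4.0, 1000.0, 275)
            )
            if rng.random() > 0.1
        }
        series = make_aligned(mapping)
        norm = normalize(series, compute_baseline(series, config))
        vals = norm.data.loc[-365:-91].dropna()
        assert abs(vals.mean()) < 1e-9
        assert abs(vals.std(ddof=1) - 1.0) < 1e-9


class TestSmoothing:
    def test_constant_series_is_fixed_point(self, config):
        series = make_aligned({t: 5000.0 for t in range(1, 61)})
        out = smooth(series, config)
        assert (out.data == 5000.0).all()

    def test_impulse_spread_over_full_window(self, config):
        mapping = {t: 0.0 for t in range(1, 61)}
        mapping[30] = 1400.0
        out = smooth(make_aligned(mapping), config)
        assert out.data.loc[30] == pytest.approx(1400.0 / 14.0)

    def test_all_missing_window_yields_missing(self, config):
        mapping = {t: 5000.0 for t in range(1, 61)}
        series = make_aligned(mapping)
        series.data.loc[20:33] = np.nan  # 14 consecutive missing days
        out = smooth(series, config)
        assert math.isnan(out.data.loc[27])  # window [20, 33] fully missing

    def test_matches_brute_force_oracle_with_missingness(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            n = int(rng.integers(1, 90))
            window = int(rng.integers(1, 20))
            vals = rng.gamma(3.0, 1500.0, n)
            vals[rng.random(n) < 0.25] = np.nan
            config = PipelineConfig(smoothing_window_days=window)
            series = make_aligned(
                {t + 1: v for t, v in enumerate(vals) if not math.isnan(v)}
            )
            series = series.replace(
                data=series.data.reindex(range(1, n + 1))
            )
            got = smooth(series, config).data.to_numpy()
            want = brute_force_smooth(list(vals), window)
            np.testing.assert_allclose(got, want, rtol=1e-12, equal_nan=True)

    def test_mean_boundedness(self, config):
        rng = np.random.default_rng(9)
        vals = rng.uniform(0, 10000, 200)
        series = make_aligned({t: v for t, v in enumerate(vals, start=1)})
        out = smooth(series, config)
        assert (out.data >= vals.min() - 1e-9).all()
        assert (out.data <= vals.max() + 1e-9).all()

    def test_trailing_window_option(self):
        config = PipelineConfig(smoothing_window_days=3, smoothing_centered=False)
        series = make_aligned({1: 3.0, 2: 6.0, 3: 9.0})
        out = smooth(series, config)
        assert out.data.loc[3] == pytest.approx((3 + 6 + 9) / 3)
        assert out.data.loc[1] == pytest.approx(3.0)

    def test_gap_in_index_counts_as_missing_inside_windows(self):
        # the excluded surgery day must not contribute to neighboring means
        config = PipelineConfig(smoothing_window_days=3)
        series = make_aligned({-1: 3.0, 1: 9.0})
        out = smooth(series, config)
        # day 0 is a true gap: windows centered at -1 and +1 each see only
        # their own observed day, and day 0 itself is not in the output
        assert out.data.loc[-1] == pytest.approx(3.0)
        assert out.data.loc[1] == pytest.approx(9.0)
        assert 0 not in out.data.index
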