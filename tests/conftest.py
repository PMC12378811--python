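import numpy as np
import pandas as pd
import pytest

from periostep import ActivitySeries, BaselineStats, NormalizedSeries, PipelineConfig


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


def make_aligned(mapping, patient_id="p1", metric="steps") -> ActivitySeries:
    """Build an aligned series from a {day_offset: value} mapping."""
    s = pd.Series(
        {int(k): float(v) for k, v in mapping.items()}, dtype=float
    )
    s.index = s.index.astype(int)
    return ActivitySeries(patient_id, metric, s)


def make_normalized(mapping, mean=4000.0, sd=1000.0, n_days=100,
                    patient_id="p1", metric="steps") -> NormalizedSeries:
    """Build a z-score series directly with an attached baseline."""
    s = pd.Series({int(k): float(v) for k, v in mapping.items()}, dtype=float)
    s.index = s.index.astype(int)
    return NormalizedSeries(patient_id, metric, s, BaselineStats(mean, sd, n_days))


def complete_series(config, value_fn, patient_id="p1") -> ActivitySeries:
    """Fully observed series over the whole perioperative window (day 0 too)."""
    offsets = np.arange(-config.pre_window_days, config.post_window_days + 1)
    vals = np.array([value_fn(int(t)) for t in offsets], dtype=float)
    return make_aligned(dict(zip(offsets, vals)), patient_id=patient_id)
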