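"""Exception hierarchy for the pipeline.

Every error raised by this package derives from :class:`PeriostepError`
so callers can catch pipeline failures without masking programming bugs.
"""


class PeriostepError(Exception):
    """Base class for all periostep errors."""


class SchemaError(PeriostepError):
    """An input table is missing a required column or has an unusable layout."""


class ExportValidationError(PeriostepError):
    """One or more rows of an activity export failed validation.

    ``rows`` holds ``(line_number, message)`` pairs, line 1 being the header.
    """

    def __init__(self, rows):
        self.rows = list(rows)
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in self.rows[:10])
        extra = "" if len(self.rows) <= 10 else f" (+{len(self.rows) - 10} more)"
        super().__init__(f"{len(self.rows)} malformed row(s): {detail}{extra}")


class MixedSeriesError(PeriostepError):
    """Records from more than one patient or metric where one was required."""


class DuplicateDayError(PeriostepError):
    """Duplicate (patient, day, metric) rows in a daily export — corrupt input."""


class InsufficientBaselineError(PeriostepError):
    """Fewer than two observed days in the baseline window."""


class DegenerateBaselineError(PeriostepError):
    """Baseline standard deviation is zero; z-normalization is undefined."""


class SegmentationError(PeriostepError):
    """Epoch segmentation cannot run (e.g. no post-operative observations)."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


class MetricsError(PeriostepError):
    """Recovery metrics cannot be computed (e.g. no post-operative data)."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


class FeatureExtractionError(PeriostepError):
    """A required clinical covariate or trajectory feature is unavailable."""


class ModelingError(PeriostepError):
    """Supervised model cannot be fit or evaluated as requested."""


class ScenarioError(PeriostepError):
    """A simulation scenario violates its parameter invariants."""


class PipelineError(PeriostepError):
    """End-to-end run failure (bad inputs, empty cohort, stage error)."""
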