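"""Exception hierarchy for the moodcast pipeline.

Signals that are part of a contract (skipped windows, undefined
correlations, untestable moderation) get their own classes so callers can
catch them without string matching.
"""


class MoodcastError(Exception):
    """Base class for all package errors."""


class ConfigError(MoodcastError):
    """Invalid configuration (bad probabilities, degenerate AR coefficient, ...)."""


class DataError(MoodcastError):
    """Malformed input data (conflicting rows, missing mandatory columns)."""


class AlignmentError(DataError):
    """Row/prediction or imputation-grid mismatch."""


class InsufficientDataError(MoodcastError):
    """Too few observations for the requested statistic."""


class UndefinedCorrelationError(MoodcastError):
    """Correlation undefined (zero variance in one of the vectors)."""


class NotTestableError(MoodcastError):
    """A sensitivity analysis cannot be run on this input (e.g., one race level)."""


class WindowSkipped(MoodcastError):
    """A rolling window had no usable training rows; logged, never fatal."""
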