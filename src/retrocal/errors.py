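"""Exception hierarchy for calibration analyses.

Every error raised by this package derives from :class:`CalibrationError`,
so callers (and the CLI exit-code mapping) can distinguish configuration
problems, data-validation failures, and degenerate statistics.
"""


class CalibrationError(Exception):
    """Base class for all retrocal errors."""


class ConfigError(CalibrationError):
    """A configuration value is missing, malformed, or inconsistent."""


class FormatError(CalibrationError):
    """An input file does not conform to the expected tabular layout."""


class ValidationError(CalibrationError):
    """Input data violate a structural invariant (e.g. non-constant
    standard score within a condition)."""


class AvailabilityError(CalibrationError):
    """A requested method has no eligible data in the corpus/study."""


class DegenerateFitError(CalibrationError):
    """The retrodiction regression cannot be fitted (zero predictor
    variance, perfect fit, or too few observations)."""


class UndefinedVarianceError(CalibrationError):
    """The t-statistic variance df/(df-2) is undefined (df <= 2)."""


class EmptyCorpusError(CalibrationError):
    """An operation produced or received a corpus with no studies."""
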