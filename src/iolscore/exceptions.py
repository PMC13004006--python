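"""Exception hierarchy for iolscore.

All errors raised by the library derive from :class:`IolScoreError` so callers
can catch library failures with a single except clause.
"""


class IolScoreError(Exception):
    """Base class for all iolscore errors."""


class ValidationError(IolScoreError, ValueError):
    """An input value is out of range, non-finite, missing or mislabelled."""


class ConfigurationError(IolScoreError, ValueError):
    """An option/strategy name or configuration object is invalid."""


class DegenerateDataError(IolScoreError, ValueError):
    """The data cannot support the requested analysis.

    Typical causes: a single outcome class, empty stratum, zero counts.
    """


class SeparationError(IolScoreError, RuntimeError):
    """Perfect or quasi-perfect separation in logistic regression.

    Raised instead of silently returning divergent coefficients.
    """


class SchemaError(IolScoreError, ValueError):
    """A tabular input does not conform to the cohort CSV schema."""


class CalibrationError(IolScoreError, RuntimeError):
    """Calibration search failed to reach the requested tolerance.

    Carries the best configuration found so far in ``best_config``.
    """

    def __init__(self, message, best_config=None, achieved=None):
        super().__init__(message)
        self.best_config = best_config
        self.achieved = achieved
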