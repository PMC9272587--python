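"""Exception hierarchy.

``ConfigurationError`` / ``InputError`` flag caller mistakes (bad parameters,
malformed data); ``AnalysisError`` flags data that cannot support the
requested computation (e.g. no artifact-free samples, rank deficiency);
``SubjectExclusion`` is the control-flow signal for a subject that must be
dropped from the group analysis, mirroring exclusion for a non-identifiable
alpha peak.
"""


class AlphaFieldError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AlphaFieldError, ValueError):
    """A configuration value violates a stated bound."""


class InputError(AlphaFieldError, ValueError):
    """Malformed or inconsistent input data."""


class AnalysisError(AlphaFieldError, RuntimeError):
    """The data cannot support the requested analysis."""


class SubjectExclusion(AlphaFieldError):
    """Subject must be excluded from the group analysis.

    Parameters
    ----------
    reason
        Human-readable exclusion reason, recorded in pipeline reports.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason
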