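"""Exception hierarchy shared across the package."""


class MrforgeError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(MrforgeError, ValueError):
    """A value violates a documented precondition."""


class ConfigurationError(MrforgeError):
    """A column map, config file, or option set is unusable."""


class ParseError(MrforgeError):
    """One or more data rows could not be parsed.

    Carries ``row_errors``: a list of (1-based line number, message) pairs so
    callers can report every bad row at once instead of failing on the first.
    """

    def __init__(self, message: str, row_errors=None):
        super().__init__(message)
        self.row_errors = list(row_errors or [])


class InsufficientInstrumentsError(InvalidInputError):
    """An estimator was given fewer instruments than it supports."""


class LDLookupError(MrforgeError, KeyError):
    """A required pairwise LD entry is absent from the supplied matrix.

    Raised rather than assuming independence: silently treating a missing
    pair as r^2 = 0 would let correlated instruments through clumping.
    """


class PipelineError(MrforgeError):
    """An end-to-end run failed; ``stage`` names the step responsible."""

    def __init__(self, message: str, stage: str | None = None):
        super().__init__(message)
        self.stage = stage
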