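"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ConfigurationError -> 2,
DataFormatError -> 3, FitError (and subclasses) -> 4.
"""


class TrapkinError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(TrapkinError, ValueError):
    """A numeric argument violates its physical or numerical precondition."""


class ConfigurationError(TrapkinError):
    """Required analysis configuration (concentrations, temperature) is missing."""


class DataFormatError(TrapkinError):
    """An input file does not conform to the expected on-disk layout."""


class FitError(TrapkinError):
    """A model fit failed in a way that cannot be silently recovered."""


class InsufficientDataError(FitError):
    """Too few observations to attempt the requested fit."""


class NoTransitionError(FitError):
    """A melt curve shows no resolvable unfolding transition."""


class StageError(TrapkinError):
    """A pipeline stage failed; carries the stage name and the partial report."""

    def __init__(self, stage: str, cause: Exception, partial_report=None):
        super().__init__(f"analysis stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.partial_report = partial_report
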