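"""Exception hierarchy shared across the package."""


class TmbkitError(Exception):
    """Base class for all package errors."""


class FormatError(TmbkitError):
    """A file does not conform to the expected tabular dialect."""


class ValidationError(TmbkitError):
    """A record violates a domain invariant (e.g. alt reads > depth)."""


class ParameterError(TmbkitError):
    """A caller-supplied parameter is outside its valid range."""


class DegenerateLikelihoodError(TmbkitError):
    """All grid likelihoods are zero; the CCF posterior is undefined."""


class DegenerateGroupingError(TmbkitError):
    """A quantile stratification rule cannot split all-equal values."""


class UndefinedComparisonError(TmbkitError):
    """A statistical comparison is undefined for the given data (e.g. no events)."""


class SeparationError(TmbkitError):
    """A regression model is refused because of perfect separation."""


class StageError(TmbkitError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
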