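"""Exception hierarchy for the ddm package."""


class DdmError(Exception):
    """Base class for all ddm-specific errors."""


class ParameterError(DdmError, ValueError):
    """A model or generator parameter is outside its valid domain."""


class ValidationError(DdmError, ValueError):
    """A cohort or record violates a structural invariant."""


class CsvFormatError(DdmError, ValueError):
    """A duration-event CSV file could not be parsed."""


class FitError(DdmError, RuntimeError):
    """A parametric fit could not be carried out on the given cohort."""


class ComparisonError(DdmError, ValueError):
    """Model fits being compared do not come from the same cohort."""


class InsufficientDataError(DdmError, ValueError):
    """Too few usable points for the requested estimate."""


class MedianUndefinedError(DdmError, ValueError):
    """The survival curve never drops to one half within the observed range."""


class DomainError(DdmError, ValueError):
    """A function was evaluated outside its support."""


class PipelineError(DdmError, RuntimeError):
    """A stage of the full analysis pipeline failed.

    The message names the stage so failures are attributable.
    """

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"{stage}: {cause}")
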