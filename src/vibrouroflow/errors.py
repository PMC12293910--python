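"""Exception hierarchy for the vibrouroflow pipeline.

Every stage raises a subclass of :class:`VibrouroflowError`, so callers can
catch pipeline failures without masking programming errors.
"""


class VibrouroflowError(Exception):
    """Base class for all pipeline errors."""


class UnsatisfiableSpecError(VibrouroflowError):
    """Rejection-sampling budget exhausted: the requested parameter overrides
    contradict the pattern rule the curve must satisfy."""


class CorruptInputError(VibrouroflowError):
    """Input contains non-finite or otherwise invalid values."""


class TooShortSignalError(VibrouroflowError):
    """Record shorter than one analysis window."""


class NoSignalError(VibrouroflowError):
    """Envelope is identically zero: nothing to detect."""


class InvalidConfigError(VibrouroflowError):
    """Internally inconsistent configuration (e.g. mel edge above Nyquist)."""


class EmptyVoidError(VibrouroflowError):
    """Flow curve carries no flow above the cutoff."""


class UndefinedCorrelationError(VibrouroflowError):
    """Pearson correlation undefined (zero variance or n < 3)."""


class InsufficientDataError(VibrouroflowError):
    """Fewer observations than the procedure requires."""


class DegenerateFoldError(VibrouroflowError):
    """A training fold contains fewer than two classes."""


class StageError(VibrouroflowError):
    """End-to-end pipeline failure, attributed to a named stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
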