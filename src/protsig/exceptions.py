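"""Exception hierarchy for protsig."""


class ProtsigError(Exception):
    """Base class for all protsig errors."""


class DataFormatError(ProtsigError, ValueError):
    """A file or table does not conform to the expected format."""


class ValidationError(ProtsigError, ValueError):
    """A value or object violates a domain invariant."""


class DegenerateDataError(ProtsigError, ValueError):
    """The data are degenerate for the requested operation (e.g. zero spread)."""


class ConvergenceError(ProtsigError, RuntimeError):
    """An iterative fit failed to converge."""


class PipelineStageError(ProtsigError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
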