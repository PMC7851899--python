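"""Exception hierarchy shared across the pipeline."""


class DcenetError(Exception):
    """Base class for all dcenet errors."""


class FormatError(DcenetError):
    """Malformed input file (duplicate ids, non-numeric cells, empty data)."""


class ValidationError(DcenetError):
    """A domain-object invariant is violated (shape, range, group size)."""


class ParameterError(DcenetError):
    """A tuning parameter is outside its allowed range."""


class StageError(DcenetError):
    """Pipeline stage failure; wraps the underlying error with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[stage: {stage}] {cause}")
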