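"""Exception hierarchy.

``ValidationError`` covers bad user inputs (malformed files, impossible
parameters) and maps to exit code 2 at the CLI; everything else under
``ChipnormError`` maps to exit code 1.
"""


class ChipnormError(Exception):
    """Base class for all package errors."""


class ValidationError(ChipnormError):
    """Invalid input data or configuration."""


class ParseError(ValidationError):
    """Malformed annotation or expression file; carries the line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f", line {line}"
        super().__init__(f"{message} ({loc})" if loc else message)
        self.path = path
        self.line = line


class PipelineError(ChipnormError):
    """A pipeline stage failed; names the stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
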