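"""Exception hierarchy shared across the pipeline."""


class CanprotError(Exception):
    """Base class for all package errors."""


class ConfigError(CanprotError, ValueError):
    """Invalid configuration value; the message names the offending field."""


class DomainError(CanprotError, ValueError):
    """An input value outside the mathematical domain of an operation."""


class InsufficientDataError(CanprotError, ValueError):
    """An operation received too few observations to proceed."""


class FormatError(CanprotError, ValueError):
    """A malformed input file; carries file path and 1-based line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(f"{message}{loc}")
        self.path = path
        self.line = line


class StageError(CanprotError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
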