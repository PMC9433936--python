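"""Exception hierarchy shared across the package."""


class GranufiltError(Exception):
    """Base class for all package errors."""


class InputError(GranufiltError):
    """A required input file or directory is missing or unreadable."""


class FormatError(GranufiltError):
    """An input file exists but does not conform to its expected dialect."""


class ParameterError(GranufiltError):
    """A configuration value or function argument is out of its valid range."""


class ScoringError(GranufiltError):
    """A gene set cannot be scored (e.g. too few detected genes)."""


class StageError(GranufiltError):
    """A pipeline stage failed; carries the stage name for CLI reporting."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
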