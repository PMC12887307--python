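"""Exception types shared across the package."""


class CesdynError(Exception):
    """Base class for all package errors."""


class FormatError(CesdynError):
    """A malformed interchange file (missing column, bad cell, duplicate id)."""

    def __init__(self, message: str, path=None, line=None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += f"{path}"
        if line is not None:
            prefix += f", line {line}"
        super().__init__(f"{prefix}: {message}" if prefix else message)


class ScenarioError(CesdynError):
    """An invalid or unsatisfiable synthetic-data scenario."""


class CalibrationError(CesdynError):
    """Temperature calibration cannot be fitted or applied."""


class AnalysisError(CesdynError):
    """An analysis precondition is violated (too few samples, invalid cycle, ...)."""
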