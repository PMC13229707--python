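"""Exception hierarchy.

Every error the pipeline raises deliberately derives from
:class:`CortifractError`, so callers can distinguish analysis failures
(dead channels, undetectable scaling regions, bad configs) from plain
programming errors.
"""

from __future__ import annotations


class CortifractError(Exception):
    """Base class for all errors raised by cortifract."""


class ParameterError(CortifractError, ValueError):
    """An argument is outside the domain an operation supports."""


class ConfigurationError(CortifractError):
    """A config file or sidecar is missing required information."""


class IngestError(CortifractError):
    """Input data could not be accepted (non-numeric cells, NaN/Inf)."""


class DegenerateSignalError(CortifractError):
    """The signal carries no usable structure (e.g. a constant/dead
    channel, for which every curve length is zero and the log-log fit is
    undefined)."""


class ScalingDetectionError(CortifractError):
    """No candidate onset reached the linearity threshold.

    Carries the best candidate found so the caller can inspect how far
    the curve was from qualifying.
    """

    def __init__(self, message: str, best_k: int, best_r2: float):
        super().__init__(message)
        self.best_k = best_k
        self.best_r2 = best_r2


class PipelineStageError(CortifractError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause
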