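"""Exception hierarchy shared across the package."""


class StrokeRecoveryError(Exception):
    """Base class for all errors raised by this package."""


class NoStepsError(StrokeRecoveryError, ValueError):
    """Raised when a foot-fault percentage is requested for a trial with no steps."""


class StandardCurveError(StrokeRecoveryError, ValueError):
    """Raised when a dilution series yields an invalid standard curve."""


class FitConvergenceError(StrokeRecoveryError, RuntimeError):
    """Raised when the one-phase-decay optimizer fails from every start.

    The best candidate found is attached as ``.best`` so callers can inspect it.
    """

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class StageError(StrokeRecoveryError, RuntimeError):
    """A pipeline stage failed; carries the stage name and CLI exit code."""

    def __init__(self, stage, exit_code, message):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
        self.exit_code = exit_code
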