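"""Exception hierarchy shared across the pipeline stages."""


class ThermoloopError(Exception):
    """Base class for all package errors."""


class ValidationError(ThermoloopError, ValueError):
    """An input value violates a documented precondition."""


class InsufficientDataError(ThermoloopError, ValueError):
    """Too few observations to perform the requested fit."""


class DegenerateDataError(ThermoloopError, ValueError):
    """Input is rank-deficient (e.g. collinear points, constant regressor)."""


class NonEllipticalFitError(ThermoloopError, RuntimeError):
    """The constrained conic fit produced no real ellipse solution.

    Carries the unconstrained algebraic conic coefficients (if computable)
    on the ``diagnostic`` attribute so the failure can be inspected.
    """

    def __init__(self, message: str, diagnostic=None):
        super().__init__(message)
        self.diagnostic = diagnostic


class ContractViolationError(ThermoloopError, RuntimeError):
    """An operation was invoked on a result that fails its required flag."""


class PipelineStageError(ThermoloopError, RuntimeError):
    """A pipeline stage failed; earlier stages' outputs are preserved."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage
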