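"""Exception hierarchy shared across the toolkit."""


class NanoqnarError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(NanoqnarError, ValueError):
    """A caller supplied an argument outside the documented domain."""


class ConfigurationError(NanoqnarError):
    """Required parameters (pair entries, charges, radii, schema) are missing."""


class EmptyParticleError(NanoqnarError):
    """An operation produced or received a particle with no atoms."""


class InfeasibleError(NanoqnarError):
    """A discrete constraint (e.g. integer charge neutrality) cannot be met."""


class MinimizationError(NanoqnarError):
    """Energy minimization diverged (atom fusion, non-finite energy)."""


class CalibrationError(NanoqnarError):
    """Wolf parameter calibration could not reach the residual tolerance."""


class UndefinedStatisticError(NanoqnarError):
    """A validation statistic has a zero denominator."""


class UndefinedGeometryError(NanoqnarError):
    """A geometric quantity is undefined (atom at the reference center)."""


class RequestValidationError(NanoqnarError):
    """One or more prediction requests failed field validation."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))
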