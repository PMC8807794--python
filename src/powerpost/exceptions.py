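"""Exception hierarchy shared across the package."""


class PowerpostError(Exception):
    """Base class for all package-specific errors."""


class InvalidModelError(PowerpostError, ValueError):
    """A model definition violates its contract (e.g. non-SPD precision)."""


class ShapeError(PowerpostError, ValueError):
    """Dimension mismatch between model components."""


class InvalidConfigError(PowerpostError, ValueError):
    """A run configuration is malformed or violates a precondition."""


class DivergenceError(PowerpostError, ArithmeticError):
    """An ODE integration left the admissible state region."""


class DegenerateSignalError(PowerpostError, ValueError):
    """A signal has zero variance so an SNR-scaled noise level is undefined."""


class EstimationError(PowerpostError, ArithmeticError):
    """An evidence estimator could not produce a finite value."""


class InvalidTraceError(PowerpostError, ValueError):
    """A sampler trace does not satisfy an estimator's requirements."""
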