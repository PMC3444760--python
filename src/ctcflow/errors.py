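"""Exception types shared across the package."""


class CTCFlowError(Exception):
    """Base class for package errors."""


class ConfigurationError(CTCFlowError):
    """Invalid geometry, parameter, or config-file input."""


class StructuralError(CTCFlowError):
    """Inconsistent point/spring bookkeeping (dangling ids, lost markers)."""


class StabilityError(CTCFlowError):
    """Numerical blow-up: NaN fields, runaway velocities, or CFL violation."""


class ConvergenceError(CTCFlowError):
    """An iterative solve failed to reach tolerance within its step budget."""


class MetricsError(CTCFlowError):
    """Shape metrics requested on a degenerate or self-intersecting contour."""
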