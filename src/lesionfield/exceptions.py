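"""Exception hierarchy for lesionfield.

All errors raised by the package derive from :class:`LesionFieldError` so
callers can catch everything with one clause.
"""


class LesionFieldError(Exception):
    """Base class for all package errors."""


class ParameterError(LesionFieldError, ValueError):
    """Invalid user-supplied parameter value."""


class GeometryError(LesionFieldError, ValueError):
    """A geometric precondition is violated (empty ROI, bad placement...)."""


class PlacementError(GeometryError):
    """Electrode placement failed (overlapping discs, too few electrodes)."""


class ConfigurationError(LesionFieldError, ValueError):
    """Inconsistent configuration (missing conductivity entry, bad config file)."""


class TopologyError(LesionFieldError, RuntimeError):
    """The conductive domain is empty or disconnected."""


class ConvergenceError(LesionFieldError, RuntimeError):
    """The iterative solver failed to reach the requested residual."""

    def __init__(self, message: str, residual: float | None = None,
                 iterations: int | None = None):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations
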