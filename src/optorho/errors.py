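"""Exception hierarchy shared across the package."""


class OptorhoError(Exception):
    """Base class for all package-specific errors."""


class ProtocolError(OptorhoError, ValueError):
    """Invalid illumination protocol (unordered pulses, out-of-range times...)."""


class ParameterError(OptorhoError, ValueError):
    """Kinetic or model parameter outside its valid domain."""


class FormatError(OptorhoError, ValueError):
    """Malformed trace / protocol file."""


class AlignmentError(OptorhoError, ValueError):
    """Traces do not share a common time grid."""


class NumericalError(OptorhoError, RuntimeError):
    """Integrator failed to reach tolerance; carries solver diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class InvariantError(OptorhoError, RuntimeError):
    """A model invariant (e.g. positivity of activities) was violated."""


class FitError(OptorhoError, RuntimeError):
    """No optimizer start converged; carries per-start diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SampleSizeError(OptorhoError, ValueError):
    """Too few cells / points for the requested estimation."""


class CalibrationError(OptorhoError, RuntimeError):
    """Weight calibration could not bracket a root (or root violates w > 1)."""


class WindowError(OptorhoError, ValueError):
    """Trace does not cover the requested evaluation window."""


class GeometryError(OptorhoError, ValueError):
    """Degenerate mask geometry (empty activation intersection...)."""


class NormalizationError(OptorhoError, ValueError):
    """Non-positive baseline or background exceeding signal."""
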