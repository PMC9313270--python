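"""Exception hierarchy."""


class PeakFluoError(Exception):
    """Base class for all package errors."""


class PlateFormatError(PeakFluoError):
    """Malformed plate or layout file."""


class InvalidDesignError(PeakFluoError):
    """Plate design violates a structural requirement (e.g. missing control)."""


class TraceMismatchError(PeakFluoError):
    """Traces that must share a cycle grid do not."""


class FitConvergenceError(PeakFluoError):
    """A model fit failed to converge or the input is degenerate."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class FlatCurveError(PeakFluoError):
    """Standard curve slope too close to zero for quantification."""
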