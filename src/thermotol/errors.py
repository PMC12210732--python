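"""Exception hierarchy used across the package."""


class ThermotolError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ThermotolError):
    """Input file cannot be mapped onto the expected columns."""


class DataError(ThermotolError):
    """Input data violates a structural invariant (e.g. non-monotone ramp)."""


class StateError(ThermotolError):
    """Operation applied to an object in the wrong state (e.g. double normalization)."""


class DetectionError(ThermotolError):
    """A feature (peak, dip, rise, admissible band) could not be detected."""


class DegeneracyError(ThermotolError):
    """Geometric degeneracy, e.g. intersecting near-parallel lines."""


class DomainError(ThermotolError):
    """Argument outside the mathematical domain of a function."""


class FitError(ThermotolError):
    """Nonlinear fit failed to converge or violated its preconditions."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class BootstrapError(ThermotolError):
    """Too many bootstrap repetitions failed to produce a fit."""
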