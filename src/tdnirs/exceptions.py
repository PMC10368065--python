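"""Exception types shared across the package."""


class TdnirsError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(TdnirsError, ValueError):
    """An input parameter is non-finite, negative, or otherwise out of range."""


class NumericalFailureError(TdnirsError, RuntimeError):
    """A numerical routine (transform inversion, quadrature) produced an
    unusable result; the message carries diagnostics."""


class IncompatibleGridError(TdnirsError, ValueError):
    """Two histograms that must share a time grid do not."""


class EmptyInputError(TdnirsError, ValueError):
    """A histogram is empty (all zero) where counts are required."""


class DegenerateGeometryError(TdnirsError, ValueError):
    """The inverse problem is ill-conditioned for this geometry."""


class ParseError(TdnirsError, ValueError):
    """A file does not conform to the expected text format."""
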