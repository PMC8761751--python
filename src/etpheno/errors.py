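"""Exception hierarchy shared across the pipeline stages."""


class EtphenoError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(EtphenoError, ValueError):
    """Sensor or sample geometry violates its physical constraints."""


class InvalidMeasurementError(EtphenoError, ValueError):
    """A raw observable is outside its physically admissible range."""


class InvalidParametersError(EtphenoError, ValueError):
    """Generator / statistics parameters violate their constraints."""

class DegenerateFitError(EtphenoError, ValueError):
    """A regression problem has no unique solution (e.g. zero spread in x)."""


class SensorFailureError(EtphenoError, ValueError):
    """No valid sensor reading is available where at least one is required."""


class ProtocolError(EtphenoError, ValueError):
    """A measurement request falls outside the study protocol."""


class NoGradientError(EtphenoError, ValueError):
    """Thermal inversion attempted without a positive source-sink gradient."""


class InputError(EtphenoError, ValueError):
    """Inconsistent or malformed inputs to an analysis operation."""


class SchemaError(EtphenoError, ValueError):
    """A file or config does not match the documented schema."""


class ConvergenceError(EtphenoError, RuntimeError):
    """An iterative solver failed to reach its tolerance."""


class IllPosedError(EtphenoError, ValueError):
    """A PDE problem lacks the boundary data needed for a unique solution."""
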