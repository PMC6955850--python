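"""Exception hierarchy shared across the package."""


class TavSurrogateError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(TavSurrogateError, ValueError):
    """Invalid configuration value (unknown scheme, unrealizable node count, ...)."""


class GeometryError(TavSurrogateError, RuntimeError):
    """A geometric construction failed (no root bracket, collinear points, ...)."""


class ConsistencyError(TavSurrogateError, ValueError):
    """Two inputs that must come from the same design do not match."""


class InvalidDeformationError(TavSurrogateError, ValueError):
    """A deformation state with non-positive volume ratio was supplied."""


class TrainingDivergenceError(TavSurrogateError, RuntimeError):
    """Optimization produced a non-finite loss."""


class StateError(TavSurrogateError, RuntimeError):
    """An operation was called on an object in the wrong state (e.g. untrained model)."""


class FormatError(TavSurrogateError, ValueError):
    """A persisted artifact is missing, corrupt, or has an unsupported version."""
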