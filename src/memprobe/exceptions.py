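"""Exception hierarchy used across the package."""


class MemprobeError(Exception):
    """Base class for all package errors."""


class ParameterError(MemprobeError, ValueError):
    """An input parameter violates its contract."""


class RangeError(MemprobeError, ValueError):
    """A value falls outside the supported range (grid, box, lags...)."""


class SelectionError(MemprobeError, ValueError):
    """An atom/molecule selection is empty or ill-formed."""


class GeometryError(MemprobeError, ValueError):
    """Degenerate geometry (zero-length vectors, too few atoms...)."""


class AnalysisError(MemprobeError, ValueError):
    """An analysis is undefined for the given input."""


class CoverageError(MemprobeError, ValueError):
    """Umbrella windows do not overlap enough to be combined."""


class ConvergenceError(MemprobeError, RuntimeError):
    """An iterative procedure failed to converge."""


class FitError(MemprobeError, RuntimeError):
    """A nonlinear fit failed from every start."""


class FormatError(MemprobeError, ValueError):
    """A file could not be parsed as the expected format."""


class ConfigError(MemprobeError, ValueError):
    """A run configuration is invalid."""
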