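"""Exception and warning types shared across the package."""


class FastWaterError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(FastWaterError, ValueError):
    """A repartition/rescale specification violates its invariants."""


class InvalidArgumentError(FastWaterError, ValueError):
    """An argument is outside the domain of the operation."""


class MissingMoleculeError(FastWaterError, KeyError):
    """The requested molecule type is absent from the topology."""


class UnsupportedTopologyError(FastWaterError, ValueError):
    """The topology cannot be edited (wrong atom count, missing mass column)."""


class InsufficientDataError(FastWaterError, ValueError):
    """Too few points/samples/replicas for the requested estimate."""


class NoSolutionError(FastWaterError, ValueError):
    """The model has no solution for the requested quantity (e.g. c = 0)."""


class DegenerateSeriesError(FastWaterError, ValueError):
    """A time series has zero variance or is otherwise degenerate."""


class DegenerateGeometryError(FastWaterError, ValueError):
    """Molecular geometry is singular (e.g. collinear sites)."""


class InvalidRangeError(FastWaterError, ValueError):
    """A fit range contains values outside the domain of the fit."""


class IntegrationError(FastWaterError, ValueError):
    """The requested integrator step violates the stability bound."""


class EmptyHistogramError(FastWaterError, ValueError):
    """All samples fell outside the histogram bins."""


class AliasingWarning(UserWarning):
    """Frame spacing too sparse for unambiguous unwrapping."""


class TruncationWarning(UserWarning):
    """An automatic window/range was truncated by the available lags."""
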