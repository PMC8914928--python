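"""Exception hierarchy shared across the pipeline stages."""


class SpatialAQError(Exception):
    """Base class for all package-specific errors."""


class InvalidCoordinateError(SpatialAQError):
    """A geographic coordinate is outside its valid domain."""


class EmptyLayerError(SpatialAQError):
    """An aggregation produced no usable (non-empty) cells."""


class EmptyDataError(SpatialAQError):
    """An input table yielded zero usable observations."""


class SchemaError(SpatialAQError):
    """An input file does not match the expected column layout."""


class DegenerateInputError(SpatialAQError):
    """Input has no variance (or is otherwise statistically degenerate)."""


class NoNeighborsError(SpatialAQError):
    """Every areal unit is isolated; a contiguity graph cannot be built."""


class InvalidObjectiveError(SpatialAQError):
    """An objective vector contains NaN or is otherwise unusable."""


class AqiRangeError(SpatialAQError):
    """A concentration or index value falls outside the covered range."""


class VariogramFitError(SpatialAQError):
    """Theoretical variogram fitting failed to converge."""


class SingularKrigingSystem(SpatialAQError):
    """The kriging system is singular (typically duplicate locations)."""


class FieldSimulationError(SpatialAQError):
    """The requested random field could not be generated."""
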