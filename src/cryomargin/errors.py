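"""Exception hierarchy shared across the package."""


class CryomarginError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(CryomarginError):
    """Degenerate or inconsistent image geometry (non-invertible affine, bad spacing)."""


class DimensionalityError(CryomarginError):
    """Volume is not three-dimensional."""


class GridIncompatibilityError(CryomarginError):
    """Two masks do not share a voxel lattice; names the offending field."""


class TransformValidityError(CryomarginError):
    """Transform is not rigid (rotation not orthonormal, or determinant != +1)."""


class DegenerateConfigurationError(CryomarginError):
    """Landmark configuration cannot determine a unique rigid transform."""


class CorrespondenceError(CryomarginError):
    """Landmark sets have mismatched point counts."""


class DegenerateMaskError(CryomarginError):
    """Mask is empty, full, or otherwise unusable for the requested operation."""


class ParameterError(CryomarginError):
    """An out-of-domain parameter value (e.g. negative margin threshold)."""


class InputError(CryomarginError):
    """Invalid statistical input (empty sample, negative cell count, ...)."""


class CapacityError(CryomarginError):
    """Exact enumeration would exceed the supported problem size."""


class InestimableError(CryomarginError):
    """A model cannot be estimated from the data given (e.g. zero events)."""


class UndefinedCorrelationError(CryomarginError):
    """Correlation undefined because an input is constant."""


class SpecError(CryomarginError):
    """A synthetic-data specification violates its own invariants."""
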