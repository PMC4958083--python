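"""Exception hierarchy shared by all pipeline stages."""


class MarrowDoseError(Exception):
    """Base class for all package errors."""


class ShapeError(MarrowDoseError, ValueError):
    """Image has the wrong dimensionality or an incompatible shape."""


class GridError(MarrowDoseError, ValueError):
    """Two objects that must share voxel geometry do not."""


class EmptyRegionError(MarrowDoseError, ValueError):
    """A region/mask that must be non-empty is empty."""


class DataError(MarrowDoseError, ValueError):
    """Input values violate a data precondition (non-finite, unsorted, negative...)."""


class DomainError(MarrowDoseError, ValueError):
    """A scalar argument is outside its mathematical domain."""


class ConfigurationError(MarrowDoseError, ValueError):
    """A required configuration entry (e.g. an S value) is missing or invalid."""


class InconsistencyError(MarrowDoseError, ValueError):
    """Quantities that must satisfy a physical balance do not."""


class UndefinedDSCError(MarrowDoseError, ValueError):
    """Dice coefficient requested for two empty masks."""
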