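"""Exception hierarchy.

Everything raised on bad user input derives from :class:`RingSpmError`
so callers (and the CLI) can catch one base class.
"""


class RingSpmError(Exception):
    """Base class for all errors raised by ringspm."""


class FormatError(RingSpmError):
    """A file on disk does not conform to the documented layout."""


class EmptyDatasetError(FormatError):
    """A manifest contains no records."""


class DuplicateRecordError(FormatError):
    """Two manifest rows resolve to the same (patient_id, slice_id)."""


class ShapeMismatchError(RingSpmError):
    """Image and mask grids have different shapes."""


class EmptyRoiError(RingSpmError):
    """A mask contains no foreground pixel."""


class GeometryError(RingSpmError):
    """A synthetic tumor could not be placed with the required margins."""


class ParameterError(RingSpmError):
    """A parameter value violates its documented domain."""


class ContractError(RingSpmError):
    """An internal data contract (symmetry, normalization, dimension) is violated."""


class ConfigError(RingSpmError):
    """A run configuration is incomplete or inconsistent."""
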