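"""Exception types shared across the pipeline."""


class VoxelskelError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(VoxelskelError, ValueError):
    """A parameter is outside its documented domain."""


class EmptyInputError(VoxelskelError, ValueError):
    """An operation that needs data received none."""


class DegenerateGeometryError(VoxelskelError, ValueError):
    """Geometry too degenerate to process (e.g. collinear cloud for PCA)."""


class ParseError(VoxelskelError, ValueError):
    """A file did not parse under the expected format."""


class TieBreakError(VoxelskelError, RuntimeError):
    """An operation hit an ambiguous tie and was not told how to resolve it."""


class ContractViolation(VoxelskelError, RuntimeError):
    """An internal precondition was violated by the caller."""
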