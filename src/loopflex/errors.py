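"""Exception hierarchy used across the package."""


class LoopflexError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(LoopflexError, ValueError):
    """Invalid input: shapes, ranges, or contract violations."""


class DimensionError(ValidationError):
    """Array dimensionality does not match the declared problem size."""


class NumericalError(LoopflexError, RuntimeError):
    """A numerical procedure diverged or produced non-finite values."""


class CapabilityError(LoopflexError, RuntimeError):
    """The request exceeds what this implementation supports (by design)."""


class ParseError(LoopflexError, ValueError):
    """A structure or data file could not be interpreted."""


class DegenerateGeometryError(LoopflexError, ValueError):
    """Geometry is singular (e.g. collinear atoms defining a dihedral)."""
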