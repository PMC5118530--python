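"""Exception hierarchy for famvc.

All famvc-raised errors derive from :class:`FamvcError` so callers can catch
the whole family with one clause. Subclasses mark which pipeline layer
rejected the input.
"""


class FamvcError(Exception):
    """Base class for all famvc errors."""


class ConfigurationError(FamvcError, ValueError):
    """Invalid simulation or run configuration (bad fractions, templates, ...)."""


class StructuralError(FamvcError, ValueError):
    """Malformed pedigree structure: cycles, unknown parents, sex conflicts."""


class DomainError(FamvcError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class TransformationError(FamvcError, ValueError):
    """A trait transformation cannot be applied (constant vector, too few values)."""


class DimensionError(FamvcError, ValueError):
    """Requested dimensionality exceeds what the data supports."""


class EstimationError(FamvcError, RuntimeError):
    """A statistical estimate cannot be produced from the given data."""


class IdentifiabilityError(EstimationError):
    """Model components are confounded and cannot be separated."""


class ModelError(FamvcError, ValueError):
    """Ill-posed model specification (non-PSD component, mismatched index, ...)."""


class ParseError(FamvcError, ValueError):
    """A data file violates its expected format."""


class ReconciliationError(FamvcError, ValueError):
    """Sample identifiers disagree between input files."""
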