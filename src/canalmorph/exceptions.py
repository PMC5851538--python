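"""Exception hierarchy shared across the package."""


class CanalmorphError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CanalmorphError):
    """A measurement table does not match the declared CSV schema."""


class ValidationError(CanalmorphError):
    """A cell or record violates a domain invariant (names the offending cell)."""


class MissingDataError(CanalmorphError):
    """A required canal or panel is absent from a specimen record."""


class InsufficientDataError(CanalmorphError):
    """Too few observations for the requested statistic."""


class UndefinedMeanError(CanalmorphError):
    """The circular mean is undefined (zero resultant vector)."""


class DegenerateVarianceError(CanalmorphError):
    """A variance component required in a denominator is exactly zero."""


class SelectionError(CanalmorphError):
    """No candidate model could be fitted."""
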