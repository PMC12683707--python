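"""Exception vocabulary shared across the pipeline.

Each stage raises a specific subclass so that CLI diagnostics can name the
failing stage and condition without string matching.
"""


class OysterdriftError(Exception):
    """Base class for all package errors."""


class InvalidGridError(OysterdriftError):
    """Degenerate or inconsistent grid specification."""


class InvalidWindowError(OysterdriftError):
    """Time window with end <= start."""


class OutOfDomainError(OysterdriftError):
    """Query position or time outside the gridded field."""


class CorruptFieldError(OysterdriftError):
    """Non-finite velocity encountered during advection."""


class DomainError(OysterdriftError):
    """Function evaluated outside its mathematical domain (e.g. T <= 0)."""


class CoverageError(OysterdriftError):
    """Temperature series does not cover the required date range."""


class NoWaterError(OysterdriftError):
    """Release geometry contains no water cells."""


class InsufficientSpaceError(OysterdriftError):
    """Not enough unoccupied water cells to place detection stations."""


class GeometryError(OysterdriftError):
    """Invalid region geometry."""


class UndefinedIndexError(OysterdriftError):
    """Connectivity index requested with zero released particles."""


class FormatError(OysterdriftError):
    """File is missing a required variable, column or attribute."""


class ValidationError(OysterdriftError):
    """File parsed but violates a declared invariant."""


class ConfigurationError(OysterdriftError):
    """Inconsistent pipeline configuration (e.g. mismatched layer tags)."""
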