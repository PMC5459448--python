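"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`GrowthfitError`, so callers (and the CLI) can catch one type.
"""


class GrowthfitError(Exception):
    """Base class for all growthfit errors."""


class DomainError(GrowthfitError, ValueError):
    """A parameter value violates the form's mathematical domain."""


class UnsupportedFormError(GrowthfitError, ValueError):
    """The requested operation is not defined for this model form."""


class DegenerateDataError(GrowthfitError, ValueError):
    """The data carry no curve information (constant, or no positive values)."""


class InsufficientDataError(GrowthfitError, ValueError):
    """Fewer observations than the form's parameter count allows."""


class MalformedFileError(GrowthfitError, ValueError):
    """An input file could not be parsed into a time series."""


class NonMonotoneTimeError(GrowthfitError, ValueError):
    """Time values contain ties and cannot be ordered strictly."""
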