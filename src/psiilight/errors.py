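"""Exception hierarchy.

All package-specific failures derive from :class:`PsiiLightError` so callers
(and the CLI) can catch one base class.
"""


class PsiiLightError(Exception):
    """Base class for all errors raised by this package."""


class InvalidMeasurementError(PsiiLightError, ValueError):
    """A fluorescence record violates an ordering or positivity precondition.

    Carries enough context to name the offending record.
    """


class DomainError(PsiiLightError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class UnderdeterminedError(PsiiLightError, ValueError):
    """Fewer distinct data points than the model requires."""


class DegenerateDataError(PsiiLightError, ValueError):
    """Response data carry no information (e.g. all-constant values)."""


class FormatError(PsiiLightError, ValueError):
    """A data file does not conform to the documented CSV schema."""
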