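"""Exception hierarchy for ventbox.

All library-raised errors derive from :class:`VentboxError` so callers can
catch the whole family; the CLI maps subfamilies onto distinct exit codes.
"""


class VentboxError(Exception):
    """Base class for all ventbox errors."""


class ValidationError(VentboxError, ValueError):
    """Invalid user input: bad fractions, negative counts, unit mismatches."""


class DomainError(VentboxError, ValueError):
    """Mathematically out-of-domain argument (e.g. non-positive volume)."""


class TableLookupError(VentboxError, KeyError):
    """A reference-table key (space class, space type, analyte) is unknown."""


class EstimationError(VentboxError):
    """The ventilation estimate is undefined for the given measurements
    (indoor steady-state CO2 at or below the outdoor level)."""


class InfeasibleLimitError(EstimationError):
    """No finite ventilation flow can reach the requested ceiling."""


class FormatError(VentboxError):
    """A sensor export does not conform to the expected tabular schema."""


class StabilizationError(VentboxError):
    """No stabilized measurement window was found in the series."""


class UndefinedRatioError(VentboxError, ZeroDivisionError):
    """Indoor/outdoor ratio is undefined because the outdoor mean is zero."""
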