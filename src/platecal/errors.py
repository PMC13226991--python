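"""Exception hierarchy.

Errors are split along the CLI's exit-code boundaries: schema/data problems
(exit 3) versus numerical failures (exit 4).
"""


class PlatecalError(Exception):
    """Base class for all package errors."""


class SchemaError(PlatecalError):
    """Malformed or invalid input data (missing columns, bad units, too few
    calibration levels, unknown sample ids)."""


class NumericalError(PlatecalError):
    """A computation could not be carried out (out-of-range inversion,
    rank-deficient design, degenerate statistics)."""


class RangeError(NumericalError):
    """A concentration or response lies outside the calibrated range."""


class DegenerateDataError(NumericalError):
    """Statistic undefined for the given data (zero variance, n too small)."""
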