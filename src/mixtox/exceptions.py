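"""Exception hierarchy for mixtox.

All library errors derive from :class:`MixtoxError` so callers (and the
CLI) can distinguish computation failures from programming errors.
"""


class MixtoxError(Exception):
    """Base class for all mixtox errors."""


class InputDataError(MixtoxError, ValueError):
    """Malformed or inconsistent input data (bad counts, mixed ids, ...)."""


class DomainError(MixtoxError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""


class UnitMismatchError(MixtoxError, ValueError):
    """Quantities that must share a unit were given different units."""


class FitError(MixtoxError, RuntimeError):
    """A dose-response model could not be fitted to the data."""


class CIError(MixtoxError, RuntimeError):
    """A bootstrap confidence interval could not be computed."""
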