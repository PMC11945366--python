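"""Exception hierarchy for the irsei package.

Exit-code mapping used by the CLI: ConfigurationError -> 2, DataError -> 3.
"""


class IrseiError(Exception):
    """Base class for all package errors."""


class ConfigurationError(IrseiError):
    """Invalid profile, band map, weights, thresholds or CLI configuration."""


class DataError(IrseiError):
    """Input data violates a precondition (unknown class codes, empty mask, ...)."""


class ContractError(IrseiError):
    """Mismatched shapes, grids or masks between operands."""


class DegenerateRangeError(DataError):
    """A min-max normalization was requested on a constant (zero-range) input."""
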