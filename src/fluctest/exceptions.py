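"""Exception hierarchy for fluctest.

All domain/validation failures derive from :class:`FluctestError` so callers
(and the CLI) can distinguish them from programming errors.
"""


class FluctestError(Exception):
    """Base class for all fluctest errors."""


class DomainError(FluctestError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class UndefinedFractionError(DomainError):
    """The stationary fraction f = k1/(k1+k2) is undefined (k1 + k2 = 0)."""


class DegenerateFractionError(DomainError):
    """CV^2 of the state fraction is undefined because f is 0 or 1."""


class DegenerateMomentError(DomainError):
    """A moment summary has a zero mean/second moment where a ratio is needed."""


class CellCapExceededError(FluctestError, RuntimeError):
    """A simulated colony would exceed the configured cell cap."""

    def __init__(self, cap: int):
        self.cap = cap
        super().__init__(
            f"colony expansion exceeded the configured cell cap of {cap} cells; "
            "reduce the expansion duration T or raise cell_cap"
        )


class ValidationError(FluctestError, ValueError):
    """Malformed input data (colony tables, configuration files)."""
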