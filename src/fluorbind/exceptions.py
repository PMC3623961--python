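"""Package-wide exception and warning types."""


class FluorbindError(Exception):
    """Base class for all fluorbind errors."""


class GridError(FluorbindError):
    """Time or wavelength grid violates a sampling requirement."""


class DegenerateIRFError(FluorbindError):
    """Instrument response function carries no counts."""


class FitError(FluorbindError):
    """A least-squares fit failed or produced a degenerate solution.

    Carries the optimiser diagnostics in ``self.diagnostics`` when available.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DomainError(FluorbindError, ValueError):
    """An input value is outside the physically meaningful domain."""


class FluorbindWarning(UserWarning):
    """Base class for all fluorbind warnings."""


class DataQualityWarning(FluorbindWarning):
    """Input data violates a soft expectation (non-monotone series, inner filter...)."""


class FitQualityWarning(FluorbindWarning):
    """A fit converged but with a caveat (boundary hit, wide CI, reduced model)."""
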