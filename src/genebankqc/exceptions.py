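"""Exception hierarchy for the curation pipeline."""


class GenebankQCError(Exception):
    """Base class for all package errors."""


class ValidationError(GenebankQCError, ValueError):
    """Input data violates a documented contract (bad cell, bad month, ...)."""


class ConfigurationError(GenebankQCError, ValueError):
    """A configuration object is internally inconsistent."""


class EstimabilityError(GenebankQCError, ValueError):
    """Requested fixed effects are not estimable (disconnected design)."""


class DegreesOfFreedomError(GenebankQCError, ValueError):
    """Fewer records than parameters to estimate."""


class InsufficientDataError(GenebankQCError, ValueError):
    """Too few records/levels for the requested computation."""
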