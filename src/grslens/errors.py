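"""Exception hierarchy."""


class GrslensError(Exception):
    """Base class for all package errors."""


class ValidationError(GrslensError):
    """An input artifact violates a contract (bad allele code, duplicate ID, ...)."""


class FitError(GrslensError):
    """A model could not be fit (collinearity, separation, non-convergence)."""
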