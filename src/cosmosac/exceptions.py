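"""Exception hierarchy for the cosmosac package."""


class CosmoSacError(Exception):
    """Base class for all package errors."""


class CosmoParseError(CosmoSacError):
    """A COSMO solvation file could not be parsed (missing section, bad field)."""


class UnsupportedDialectError(CosmoParseError):
    """Input text is recognizably in a dialect this parser does not handle."""


class ProfileFormatError(CosmoSacError):
    """A sigma-profile table violates the tabular exchange format."""


class ValidationError(CosmoSacError):
    """A domain object violates one of its invariants."""


class ConfigurationError(CosmoSacError):
    """A parameter set is incomplete or inconsistent for the requested model."""


class ConvergenceError(CosmoSacError):
    """An iterative solver failed to reach its tolerance."""

    def __init__(self, message, residual_history=None):
        super().__init__(message)
        self.residual_history = residual_history


class BracketError(CosmoSacError):
    """A scalar root could not be bracketed on the search interval."""


class SolverError(CosmoSacError):
    """A nonlinear solve (e.g. LLE tie line) failed after multistart."""


class FitError(CosmoSacError):
    """Parameter estimation could not evaluate or minimize the objective."""
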