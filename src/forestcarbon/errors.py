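"""Exception hierarchy shared across the pipeline."""


class ForestCarbonError(Exception):
    """Base class for all package errors."""


class ValidationError(ForestCarbonError):
    """Input value or schema violates a stated precondition."""


class ConfigurationError(ForestCarbonError):
    """A configuration object is internally inconsistent."""


class IntegrityError(ForestCarbonError):
    """Referential integrity between tables is broken (orphans, duplicates)."""


class UnknownSpeciesError(ForestCarbonError, KeyError):
    """No allometry coefficients are available for a species code."""


class MissingDataError(ForestCarbonError):
    """A required measurement or raster cell is absent; the pair is excluded."""


class ConvergenceError(ForestCarbonError):
    """An iterative fit failed to converge; carries the optimizer trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace
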