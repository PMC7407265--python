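"""Exception hierarchy shared across the pipeline stages."""


class DropquantError(Exception):
    """Base class for all dropquant errors."""


class InvalidParameterError(DropquantError, ValueError):
    """A configuration or function parameter is out of its valid range."""


class InsufficientDataError(DropquantError):
    """Too few observations to perform the requested computation."""


class SaturationError(DropquantError):
    """No negative droplets: the Poisson rate is unbounded. Dilute the sample."""


class InvalidCountsError(DropquantError, ValueError):
    """Droplet counts violate a partition constraint (e.g. negatives > total)."""


class MissingDataError(DropquantError):
    """A required measurement (e.g. a Ct value) is absent."""


class AlignmentError(DropquantError):
    """Two call sets do not cover the same sample identifiers."""


class ValidationError(DropquantError):
    """An input table violates a structural rule (duplicates, missing labels)."""


class UndefinedStatisticError(DropquantError):
    """A statistic is undefined for this input (e.g. kappa with degenerate marginals)."""
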