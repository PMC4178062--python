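"""Exception hierarchy shared across the package."""


class StockIdError(Exception):
    """Base class for all stockid errors."""


class ConfigurationError(StockIdError, ValueError):
    """Invalid synthetic-data or pipeline configuration; names the field."""


class SchemaError(StockIdError, ValueError):
    """Input table violates the documented CSV schema."""


class DegenerateDesignError(StockIdError, ValueError):
    """A regression design is degenerate (e.g. constant predictor)."""


class DegenerateInputError(StockIdError, ValueError):
    """Input carries no usable variation (e.g. all-zero distances)."""


class InsufficientDataError(StockIdError, ValueError):
    """Too few observations in a group or cell for the requested analysis."""


class RankDeficiencyError(StockIdError, ValueError):
    """Response matrix is rank deficient; lists the collinear columns."""


class SingularMatrixError(StockIdError, ValueError):
    """A scatter/covariance matrix is singular or not positive definite."""


class FattyAcidNameError(StockIdError, ValueError):
    """Fatty-acid name does not follow Cx:y[wz] nomenclature."""
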