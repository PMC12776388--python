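"""Exception hierarchy for cellnp."""


class CellnpError(Exception):
    """Base class for all cellnp-specific errors."""


class SchemaError(CellnpError):
    """A required column is missing or the column mapping is invalid."""


class TableParseError(CellnpError):
    """A data file contains malformed rows; the message names the rows."""


class ResponseDomainError(CellnpError):
    """Nonpositive responses encountered where logarithms are required."""


class EmptySelectionError(CellnpError):
    """A condition key matched no cells."""


class PairingError(CellnpError):
    """Multi-time-point selection requested on unpaired (long-layout) data."""


class InsufficientDataError(CellnpError):
    """Too few observations to fit the requested model."""


class DegenerateCovarianceError(CellnpError):
    """Sample covariance is singular or numerically ill-conditioned."""


class DimensionMismatchError(CellnpError):
    """Hypothesis pair or observation dimensions disagree."""


class NotSPDError(CellnpError):
    """A covariance matrix is not symmetric positive-definite."""


class DegenerateStatisticError(CellnpError):
    """The two hypotheses coincide; the test statistic is identically zero."""


class UnsupportedDimensionError(CellnpError):
    """Deterministic quadrature is only provided for N in {1, 2}."""
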