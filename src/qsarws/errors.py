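"""Exception hierarchy shared across the workflow modules."""


class QsarError(Exception):
    """Base class for all errors raised by this package."""


class InvalidEndpointError(QsarError):
    """IC50 missing or non-positive where a potency endpoint is required."""


class CensoredEndpointError(QsarError):
    """A censored record (no definitive IC50) was used where a numeric endpoint is required."""


class EmptyPoolError(QsarError):
    """Descriptor pruning removed every column."""


class NamedColumnError(QsarError, KeyError):
    """A named descriptor column is absent from the table."""


class SchemaError(QsarError):
    """Descriptor names or dimensions do not match between model and data."""


class SingularDesignError(QsarError):
    """Rank-deficient design matrix in an OLS fit."""


class DegeneratePCAError(QsarError):
    """Zero-variance descriptor matrix; principal components undefined."""


class UndefinedStatisticError(QsarError):
    """A statistic is undefined for the given inputs (e.g. zero-variance response)."""


class SearchError(QsarError):
    """Descriptor-subset search cannot run (pool too small, bad config)."""


class NoAnalogueError(QsarError):
    """No eligible training analogue for a read-across query."""


class SyntheticSpecError(QsarError):
    """Infeasible synthetic-data specification."""
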