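"""Exception hierarchy for qsarforge."""


class QsarError(Exception):
    """Base class for all qsarforge errors."""


class ConfigurationError(QsarError):
    """An invalid configuration object or parameter value."""


class TableError(QsarError):
    """A malformed descriptor table (missing values, duplicate names, ...)."""


class EmptyTableError(TableError):
    """A reduction step removed every descriptor column."""


class SplitError(QsarError):
    """Train/test partitioning could not satisfy its invariants."""


class SingularFitError(QsarError):
    """A regression design matrix was rank deficient."""


class UndefinedStatisticError(QsarError):
    """A statistic is undefined for the given inputs (zero variance etc.)."""


class DomainError(QsarError):
    """Applicability-domain computation failed (degenerate geometry etc.)."""
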