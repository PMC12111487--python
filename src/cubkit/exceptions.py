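"""Exception hierarchy shared across the package."""


class CodonUsageError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CodonUsageError):
    """Invalid configuration: unknown genetic code, infeasible simulation spec, empty reference set."""


class InputError(CodonUsageError):
    """Unreadable or empty input file."""


class StatisticUndefinedError(CodonUsageError):
    """A statistic has no defined value for this input (e.g. zero included codons)."""


class InsufficientDataError(CodonUsageError):
    """Too few observations to run the procedure (e.g. <10 genes for decile grouping)."""
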