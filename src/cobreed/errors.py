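"""Exception hierarchy shared across the package."""


class CobreedError(Exception):
    """Base class for all package errors."""


class ConfigError(CobreedError, ValueError):
    """Invalid simulation or analysis configuration."""


class DataError(CobreedError, ValueError):
    """Malformed or inconsistent resighting data."""


class InvalidDyadError(CobreedError, ValueError):
    """A dyad was requested with i == j."""


class DegenerateTableError(CobreedError, ValueError):
    """A contingency-table margin is zero; the chi-square is undefined."""


class NonIdentifiableError(CobreedError, ValueError):
    """The outcome carries no information (all observed values identical)."""


class DegenerateSummaryError(CobreedError, ValueError):
    """Posterior draws have zero variance; z-score undefined."""


class InsufficientDataError(CobreedError, ValueError):
    """Too few individuals or records to run an analysis stage."""


class PermutationFailureError(CobreedError, RuntimeError):
    """Too many permutation replicates failed to produce a statistic."""
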