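"""Exception hierarchy shared across the package."""


class EnzthermError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(EnzthermError):
    """An input table is missing a required column or has a malformed header."""


class ValidationError(EnzthermError):
    """A row or value violates the data model (e.g. non-positive kcat/Km)."""


class ConsistencyError(EnzthermError):
    """Cross-record contradiction, e.g. one sequence_id mapping to two sequences."""


class ConfigError(EnzthermError):
    """An invalid configuration value (unknown scheme, bad bounds, bad n, ...)."""


class UndefinedResultError(EnzthermError):
    """A statistic is undefined for the given input (e.g. all-zero differences)."""


class LeakageError(EnzthermError):
    """A validation sequence leaked into a training set."""
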