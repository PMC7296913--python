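"""Exception hierarchy shared across the package.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class ChromdiffError(Exception):
    """Base class for all package errors."""


class ConfigError(ChromdiffError):
    """Invalid configuration: a named invariant is violated."""


class DataError(ChromdiffError):
    """Input data is missing, malformed, or inconsistent."""


class UsageError(ChromdiffError):
    """An operation was called with arguments violating its contract."""
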