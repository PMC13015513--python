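"""Exception hierarchy mapped to CLI exit codes.

Exit-code contract: 0 success, 2 usage/config error, 3 data error
(unreadable or degenerate input), 4 estimation failure.
"""


class RefnormError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(RefnormError):
    """Bad configuration: unknown key, type mismatch, invalid flag combination."""

    exit_code = 2


class DataError(RefnormError):
    """Unreadable, malformed, or structurally invalid input data."""

    exit_code = 3


class BedParseError(DataError):
    """Malformed BED line; message names the offending line number."""


class EstimationError(RefnormError):
    """A parameter could not be estimated from the data provided
    (e.g. constant reference signals, no enrichment over background)."""

    exit_code = 4
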