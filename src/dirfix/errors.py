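"""Exception hierarchy shared across the package.

CLI exit-code mapping: :class:`UsageError` cases are handled by click
(exit 2); every :class:`DirfixError` maps to exit 1.
"""


class DirfixError(Exception):
    """Base class for all package errors."""


class ConfigError(DirfixError):
    """Invalid configuration: bad geometry, missing column, unknown name."""


class DataError(DirfixError):
    """Malformed input data: non-numeric cells, duplicate onsets, bad masks."""


class ContractError(DirfixError):
    """A caller violated a documented precondition (aligned lengths etc.)."""
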