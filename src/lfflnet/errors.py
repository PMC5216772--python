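"""Exception hierarchy shared across the package.

``ConfigError`` maps to CLI exit code 2, the data-level errors to exit code 3.
"""


class LFFLError(Exception):
    """Base class for all package errors."""


class ConfigError(LFFLError):
    """Invalid or incomplete configuration (bad paths, out-of-range parameters)."""


class DataError(LFFLError):
    """Input data violates a precondition (too few samples, missing transcript, ...)."""


class ParseError(DataError):
    """A file could not be parsed; the message names the offending line."""


class ClassConflictError(DataError):
    """One transcript id is implied to belong to two different node classes."""
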