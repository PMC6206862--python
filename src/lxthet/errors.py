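"""Exception hierarchy.

``ConfigError``/``SchemaError``/``ParseError`` signal problems with user
inputs; ``AnalysisError`` signals a statistical precondition violation
(too few replicates, no unlinked pairs, constant phenotype, ...).
"""


class LxthetError(Exception):
    """Base class for all package errors."""


class ConfigError(LxthetError):
    """Invalid configuration value; the message names the offending field."""


class SchemaError(LxthetError):
    """A table violates its schema (missing column, duplicate key, bad code)."""


class ParseError(LxthetError):
    """A file could not be parsed; the message carries row/column context."""


class AnalysisError(LxthetError):
    """A statistical operation's preconditions are not met."""
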