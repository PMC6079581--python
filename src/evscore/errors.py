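"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes (config 2, data 3, internal 4)
so shell callers can distinguish a bad invocation from bad input.
"""


class EvScoreError(Exception):
    """Base class for all package errors."""


class ConfigError(EvScoreError):
    """Invalid configuration: unknown tokenizer, missing resource, bad toggle."""


class DataError(EvScoreError):
    """Invalid or degenerate input data."""


class ParseError(DataError):
    """Malformed structured input (CoNLL-U, bracketed trees, network files)."""


class DimensionError(EvScoreError):
    """Vector/matrix dimension mismatch."""


class GenerationError(DataError):
    """A synthetic-data generator could not satisfy its constraints."""


class ValidationError(EvScoreError):
    """A value violated a documented contract (e.g. feature outside [0, 1])."""
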