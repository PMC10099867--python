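"""Exception hierarchy shared across the toolkit.

Every error raised by the library derives from :class:`CqtError` so callers
(and the CLI) can distinguish toolkit failures from programming errors.
"""


class CqtError(Exception):
    """Base class for all toolkit errors."""


class InvalidArgumentError(CqtError, ValueError):
    """A scalar argument violates a precondition (non-finite, out of range)."""


class DegenerateInputError(CqtError, ValueError):
    """Input data carry no usable variation (zero variance, n too small)."""


class IdenticalResponsesError(CqtError, ValueError):
    """Two temperature-response curves coincide everywhere."""


class SchemaError(CqtError, ValueError):
    """A CSV file does not match the expected column schema."""


class LinkageError(CqtError, ValueError):
    """A catalysed reaction references an unknown uncatalysed partner."""


class ConfigError(CqtError, ValueError):
    """A generator configuration violates its invariants."""
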