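"""Shared exception hierarchy.

All package errors derive from :class:`CnvAssocError` so callers (and the
CLI) can distinguish input problems (:class:`ValidationError`,
:class:`ParseError`, :class:`ConfigError` -> exit code 1) from runtime
failures (exit code 2).
"""


class CnvAssocError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(CnvAssocError):
    """Input data violates a documented invariant."""


class ParseError(ValidationError):
    """A text input could not be parsed; the message names the line."""


class ConfigError(ValidationError):
    """A run or simulation configuration is inconsistent."""


class DegenerateInputError(CnvAssocError):
    """A statistical routine received an input it cannot fit
    (e.g. a logistic model with no carriers at all)."""
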