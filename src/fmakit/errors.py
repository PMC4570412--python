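"""Exception hierarchy.

All validation failures raise :class:`ValidationError` (or a subclass) so
callers can distinguish bad data from programming errors; numeric-parameter
misuse raises :class:`ParameterError`.
"""


class FmakitError(Exception):
    """Base class for all package errors."""


class ValidationError(FmakitError, ValueError):
    """A domain object or file violates an invariant."""


class ParseError(ValidationError):
    """A recording container could not be parsed; names the offending stream."""


class ParameterError(FmakitError, ValueError):
    """An operation was called with an invalid parameter value."""


class DegenerateInputError(FmakitError, ValueError):
    """Input is structurally valid but too degenerate for the operation."""


class TrainingError(FmakitError, RuntimeError):
    """A classifier could not be trained on the given dataset."""
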