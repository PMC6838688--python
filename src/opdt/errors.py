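"""Exception hierarchy for opdt.

All validation failures raise subclasses of :class:`OpdtError` so callers can
distinguish bad inputs from genuine computation failures (the CLI maps them to
distinct exit codes).
"""


class OpdtError(Exception):
    """Base class for all opdt errors."""


class InvalidArgumentError(OpdtError, ValueError):
    """An argument violates a documented precondition."""


class RangeError(OpdtError, ValueError):
    """A query lies outside the calibrated / recorded range."""


class NoSeparationError(OpdtError):
    """The sorted detection statistics show no sub/supra-threshold gap."""


class NonIdentifiableError(OpdtError):
    """The response curve does not constrain the sigmoid parameters."""


class UndefinedProbabilityError(OpdtError):
    """A conditional probability was requested on an empty conditioning set."""


class SchemaError(OpdtError):
    """A session container does not match the expected on-disk layout."""
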