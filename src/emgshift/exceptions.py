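"""Exception hierarchy.

``ValueError`` subclasses mark caller mistakes (bad arguments, malformed
files); :class:`NumericalError` marks conditioning failures that usually
respond to a larger ridge.
"""


class EmgShiftError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(EmgShiftError, ValueError):
    """An argument violates an operation's precondition."""


class DataError(EmgShiftError, ValueError):
    """Input data are structurally valid but unusable (e.g. empty class)."""


class FormatError(EmgShiftError, ValueError):
    """A file does not match its declared layout or schema."""


class NumericalError(EmgShiftError, RuntimeError):
    """A linear-algebra step failed (singular or indefinite matrix)."""
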