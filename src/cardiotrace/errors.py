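"""Exception types used across the package.

The CLI maps these onto distinct exit codes, so library code should raise
the most specific type that applies.
"""


class CardiotraceError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(CardiotraceError, ValueError):
    """A caller-supplied argument violates a documented precondition."""


class InvalidDataError(CardiotraceError, ValueError):
    """Input data is structurally readable but unusable (non-finite pixels,
    empty stacks, empty masks, ...)."""


class DegenerateDataError(CardiotraceError, ValueError):
    """Data is valid but degenerate for the requested computation
    (e.g. a zero-variance spectrum cannot be correlated)."""


class InvalidConfigError(CardiotraceError, ValueError):
    """A configuration file or flag set is malformed or out of range."""
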