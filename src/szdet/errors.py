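"""Exception types shared across the package."""


class SzdetError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(SzdetError, ValueError):
    """A configuration object violates its invariants."""


class InvalidInputError(SzdetError, ValueError):
    """Input data violates an operation's precondition."""


class DegenerateDataError(SzdetError, ValueError):
    """Data is degenerate for the requested operation (e.g. zero variance)."""
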