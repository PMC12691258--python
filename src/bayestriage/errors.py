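"""Exception types shared across the package."""


class BayestriageError(Exception):
    """Base class for all package errors."""


class ValidationError(BayestriageError, ValueError):
    """An input failed validation; the message names the offending field."""


class UndefinedQuantityError(BayestriageError, ArithmeticError):
    """A requested quantity has a zero denominator and is mathematically undefined."""


class InternalInconsistencyError(BayestriageError, AssertionError):
    """Two independent computation routes disagreed beyond tolerance."""
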