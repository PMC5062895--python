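"""Exception hierarchy shared across the kinetics modules."""


class SmokekinError(Exception):
    """Base class for all package-specific errors."""


class DomainError(SmokekinError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class DestructionRegimeError(DomainError):
    """A yield above the reference concentration where decay was assumed."""


class InsufficientDataError(SmokekinError, ValueError):
    """Too few (or degenerate) data points for the requested fit."""


class NoPeakError(SmokekinError, ValueError):
    """A temperature-yield series with no usable maximum."""


class EmptyDestructionWindowError(SmokekinError, ValueError):
    """No temperatures above the yield peak: nothing to fit."""


class ParseError(SmokekinError, ValueError):
    """A malformed input file; the message lists offending lines."""
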