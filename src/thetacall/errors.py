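"""Exception types shared across the package."""


class ThetacallError(Exception):
    """Base class for package errors."""


class DomainError(ThetacallError, ValueError):
    """An input value lies outside the mathematical domain of an operation."""


class UndefinedWindowError(ThetacallError):
    """The requested window contains no usable sites."""


class InsufficientHaplotypesError(ThetacallError):
    """Fewer than two haplotypes: diversity is undefined."""


class UndefinedEstimateError(ThetacallError):
    """The estimator is undefined for this window summary (e.g. zero variance)."""


class UndefinedProportionError(ThetacallError):
    """A proportion over an empty set was requested."""
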