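"""Exception hierarchy shared across the pipeline."""


class NanoSIPError(Exception):
    """Base class for all package errors."""


class InputDomainError(NanoSIPError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ConfigurationError(NanoSIPError, ValueError):
    """An experiment or simulation configuration is internally inconsistent.

    Raised e.g. when the labeled substrate pool is not enriched above the
    unlabeled control mean, so the tracer cannot trace.
    """


class MeasurementInvalidError(NanoSIPError, ValueError):
    """A single cell's raw measurement cannot be reduced to an isotope ratio.

    The cell is flagged and excluded from denominators, never silently
    dropped by the math layer.
    """


class InsufficientControlError(NanoSIPError, ValueError):
    """Too few unlabeled control cells to estimate mean and SD."""


class FormatError(NanoSIPError, ValueError):
    """A delimited input table is structurally unusable (header-level)."""


class UndefinedResultError(NanoSIPError, ArithmeticError):
    """A summary is undefined for the given data (e.g. empty denominator)."""
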