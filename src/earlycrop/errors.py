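"""Exception types shared across the package."""


class EarlycropError(Exception):
    """Base class for package errors."""


class ConfigurationError(EarlycropError, ValueError):
    """Invalid generator or pipeline configuration."""


class UndefinedValueError(EarlycropError, ValueError):
    """An index or metric is undefined for the given inputs (e.g. zero denominator)."""


class UnusablePixelError(EarlycropError, ValueError):
    """A pixel has no valid observations and cannot be gap-filled."""


class DegeneratePhenologyError(EarlycropError, ValueError):
    """No value in the series exceeds its own median; season timing is undefined."""


class SchemaError(EarlycropError, ValueError):
    """Feature schema mismatch between training and prediction."""
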