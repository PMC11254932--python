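"""Exception hierarchy.

Every error raised by phyllon derives from :class:`PhyllonError` so callers
can catch the whole family; most also derive from ``ValueError`` because they
signal invalid inputs rather than internal faults.
"""


class PhyllonError(Exception):
    """Base class for all phyllon errors."""


class InvalidDeltaError(PhyllonError, ValueError):
    """A delta value below -1000 permil (impossible: negative heavy-isotope content)."""


class IncompleteRecordError(PhyllonError, ValueError):
    """An incubation record is missing a field required by the requested rate."""


class ZeroDurationError(PhyllonError, ValueError):
    """Incubation duration is zero or negative."""


class InvalidWindowError(PhyllonError, ValueError):
    """A time window with t2 <= t1."""


class EmptyPoolError(PhyllonError, ValueError):
    """A substrate pool with zero total concentration."""


class NegativeNitrateError(PhyllonError, ValueError):
    """NOx below NO2: impossible nitrogen speciation, never clipped silently."""


class UndefinedRatioError(PhyllonError, ValueError):
    """A ratio whose denominator is zero or negative."""


class UnitError(PhyllonError, ValueError):
    """Unknown or dimensionally incompatible unit strings."""


class DesignError(PhyllonError, ValueError):
    """A statistical design that cannot be analyzed (empty cell, one group, no residual df)."""


class ConfigError(PhyllonError, ValueError):
    """Invalid or incomplete run configuration."""


class SchemaError(PhyllonError, ValueError):
    """An input table that fails schema validation; carries row-level messages."""

    def __init__(self, messages):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))
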