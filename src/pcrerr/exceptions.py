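"""Exception hierarchy shared by all pcrerr modules."""


class PcrErrError(Exception):
    """Base class for all errors raised by pcrerr."""


class DimensionError(PcrErrError):
    """Array shapes or lengths are incompatible with the requested operation."""


class RankError(PcrErrError):
    """The requested number of components exceeds the available rank."""


class DegreesOfFreedomError(PcrErrError):
    """A variance denominator would be zero or negative."""


class ConfigurationError(PcrErrError):
    """A required piece of model state or configuration is missing or invalid."""


class ValidationError(PcrErrError):
    """Input values violate a precondition (non-finite, empty, out of range...)."""
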