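"""Exception types shared across the package."""


class MelcoreError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MelcoreError):
    """A simulation or run configuration violates an invariant."""


class FormatError(MelcoreError):
    """An input file violates its format contract."""


class InsufficientDataError(MelcoreError):
    """Too few observations, groups or sequences for the statistic."""


class UndefinedStatisticError(MelcoreError):
    """The statistic is mathematically undefined for this input."""


class ParameterError(MelcoreError):
    """An operation parameter is outside its admissible range."""
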