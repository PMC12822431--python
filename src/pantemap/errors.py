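"""Exception hierarchy.

``ParameterError`` signals a bad argument or configuration value (CLI exit
code 2); ``DataError`` signals malformed or degenerate input data (exit
code 3).
"""


class PantemapError(Exception):
    """Base class for all package errors."""


class ParameterError(PantemapError, ValueError):
    """An argument is outside its documented domain."""


class ConfigError(ParameterError):
    """A configuration file is invalid (unknown key, bad value)."""


class DataError(PantemapError, ValueError):
    """Input data violate a documented precondition."""


class SaturationError(DataError):
    """Sequence divergence too high for the correction model (p >= 0.75)."""


class DependencyError(PantemapError, RuntimeError):
    """A pipeline stage was requested before its upstream output exists."""
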