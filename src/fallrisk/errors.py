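"""Exception hierarchy for the fallrisk package."""


class FallriskError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FallriskError):
    """A configuration value is invalid or out of its allowed range."""


class FormatError(FallriskError):
    """An input file does not conform to the expected dialect."""


class SizeError(FallriskError):
    """An array or sequence has the wrong shape or length."""


class DataError(FallriskError):
    """Input data are empty, inconsistent, or otherwise unusable."""


class StateError(FallriskError):
    """An operation was called on an object in the wrong state."""
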