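"""Exception hierarchy."""


class OmicsurvError(Exception):
    """Base class for package errors."""


class ConfigError(OmicsurvError, ValueError):
    """Invalid configuration value; the message names the offending field."""


class ValidationError(OmicsurvError, ValueError):
    """A data object violates a domain invariant."""


class ParseError(OmicsurvError, ValueError):
    """A file could not be parsed; the message carries file/line context."""
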