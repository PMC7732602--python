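"""Exception hierarchy shared by all pipeline stages."""


class MethylClassError(Exception):
    """Base class for all package errors."""


class ValidationError(MethylClassError, ValueError):
    """Input data violates a documented invariant (bad value, duplicate ID...)."""


class ConfigError(MethylClassError, ValueError):
    """A configuration object or file is inconsistent or incomplete."""


class ParseError(MethylClassError, ValueError):
    """A delimited-text input could not be parsed; names the offending cell."""
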