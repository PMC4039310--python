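"""Exception types shared across the toolkit."""


class OncointError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(OncointError, ValueError):
    """A simulation or pipeline configuration is invalid."""


class InputError(OncointError, ValueError):
    """An input table violates its contract (negative counts, missing columns, ...)."""


class ParseError(OncointError, ValueError):
    """A file could not be parsed; message carries the offending location."""
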