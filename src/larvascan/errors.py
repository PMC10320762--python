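"""Exception hierarchy shared across the pipeline."""


class LarvascanError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(LarvascanError):
    """Invalid simulation or scan configuration."""


class ParameterError(LarvascanError):
    """A runtime parameter is outside its valid domain."""


class ParseError(LarvascanError):
    """Malformed input file; message names the offending line where known."""


class ValidationError(LarvascanError):
    """A table violates a schema invariant."""


class ScanError(LarvascanError):
    """A test procedure cannot be run on the given samples."""


class UndefinedTestError(ScanError):
    """A contingency table has a zero marginal, so the test is undefined."""
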