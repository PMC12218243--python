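"""Exception hierarchy shared across the pipeline."""


class SsumixError(Exception):
    """Base class for all pipeline errors."""


class FormatError(SsumixError):
    """Malformed or inconsistent input file."""


class ConfigurationError(SsumixError):
    """Invalid parameterization or missing required configuration."""


class UsageError(SsumixError):
    """An operation was called with arguments violating its contract."""
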