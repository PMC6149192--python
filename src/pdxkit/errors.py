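"""Exception types shared across the toolkit."""


class PdxkitError(Exception):
    """Base class for all pdxkit errors."""


class ConfigurationError(PdxkitError, ValueError):
    """A configuration value is outside its documented domain."""


class ValidationError(PdxkitError, ValueError):
    """An input table or record violates its contract."""


class AnalysisError(PdxkitError, RuntimeError):
    """A computation cannot proceed (degenerate input, undefined result)."""
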