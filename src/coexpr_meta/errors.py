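"""Exception types shared across the package."""


class CoexprError(Exception):
    """Base class for all package errors."""


class ValidationError(CoexprError, ValueError):
    """Malformed input data or configuration."""


class AnalysisError(CoexprError, ValueError):
    """A statistical operation was called outside its domain."""
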