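"""Exception hierarchy shared across the pipeline stages."""


class EnfError(Exception):
    """Base class for all package errors."""


class ValidationError(EnfError):
    """An input table or configuration failed validation."""


class MissingDataError(EnfError):
    """A required lookup (coefficient, dilution rule, profile) is absent."""
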