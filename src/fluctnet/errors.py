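"""Exception hierarchy.

Validation errors (bad inputs, contract violations detectable before any
compute) are distinguished from runtime failures so the CLI can map them to
distinct exit codes.
"""


class FluctNetError(Exception):
    """Base class for all package errors."""


class ValidationError(FluctNetError):
    """Input or configuration violates a documented precondition."""


class SelectionError(ValidationError):
    """An atom selection query references unknown fields or entities."""
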