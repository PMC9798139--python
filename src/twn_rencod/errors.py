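"""Exception hierarchy.

Validation errors (bad inputs, broken invariants) are distinguished from
format errors (unreadable files) so the CLI can map them to exit codes.
"""


class TwnRencodError(Exception):
    """Base class for all package errors."""


class ValidationError(TwnRencodError):
    """An input violates a documented invariant or precondition."""


class InputFormatError(TwnRencodError):
    """A file could not be parsed as the declared format."""
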