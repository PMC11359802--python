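"""Exception types shared across the package."""


class ChaiError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ChaiError, ValueError):
    """An input violates a documented precondition or invariant."""


class FormatError(ChaiError, ValueError):
    """A file could not be parsed in the expected tabular format."""
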