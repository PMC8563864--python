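"""Exception hierarchy shared across the package."""


class DegnetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DegnetError):
    """A file does not conform to the expected layout (missing columns, short lines)."""


class ParseError(DegnetError):
    """A value could not be parsed; carries the offending line number where known."""


class IntegrityError(DegnetError):
    """Data violates an invariant (duplicate keys, inconsistent node sets)."""


class EmptyNetworkError(DegnetError):
    """An operation produced or received a network with an empty node side."""
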