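"""Exception types shared across the package."""


class ColdTmeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ColdTmeError, ValueError):
    """A file could not be parsed: malformed structure, duplicate ids,
    non-numeric cells, truncated lines."""


class ValidationError(ColdTmeError, ValueError):
    """Parsed data violate a domain invariant (wrong value space,
    missing gene lengths, inconsistent annotations, ...)."""
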