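"""Exception hierarchy used across the package."""


class ArchmorphError(Exception):
    """Base class for all package errors."""


class MeshIOError(ArchmorphError, IOError):
    """Raised for unreadable, truncated or unwritable mesh files."""


class ValidationError(ArchmorphError, ValueError):
    """Raised when inputs violate a documented precondition."""


class EmptyResultError(ArchmorphError):
    """Raised when a geometric query produces no result (e.g. plane misses mesh)."""
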