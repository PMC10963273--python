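"""Exception hierarchy.

``DomainError`` marks violated scientific preconditions (shape mismatches,
non-positive voxel sizes, invalid p-values); ``ConfigurationError`` marks
invalid or incomplete run configuration (unknown keys, missing metadata).
Both derive from ``ValueError`` so callers may catch broadly.
"""


class FosmapError(Exception):
    """Base class for all package errors."""


class DomainError(FosmapError, ValueError):
    """A scientific precondition on the inputs is violated."""


class ConfigurationError(FosmapError, ValueError):
    """Run configuration is invalid, contradictory or incomplete."""


class VolumeIOError(FosmapError, OSError):
    """A volume file could not be read or written."""
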