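"""Exception hierarchy.

All domain failures derive from :class:`CoreAlignError` so callers (and the
CLI) can distinguish expected pipeline failures from programming errors.
"""


class CoreAlignError(Exception):
    """Base class for all corealign domain errors."""


class FormatError(CoreAlignError):
    """Unreadable, mixed, or unsupported image file format."""


class GeometryError(CoreAlignError):
    """Inconsistent image geometry (e.g. non-uniform slice spacing)."""


class NoEdgeError(CoreAlignError):
    """A 1D edge search found no edge (constant or too-short profile)."""


class DegenerateGeometryError(CoreAlignError):
    """Collinear boundary points: no unique circle exists."""


class NoObjectError(CoreAlignError):
    """No stable slice segment found; alignment correction impossible."""


class SpecError(CoreAlignError):
    """Invalid synthetic-object specification."""


class DegenerateTestError(CoreAlignError):
    """Statistical test undefined (e.g. zero sample variance)."""
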