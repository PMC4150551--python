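"""Exception hierarchy for cementscan.

All package-specific failures derive from :class:`CementScanError` so callers
(and the CLI exit-code mapping) can distinguish validation problems from
genuine bugs.
"""


class CementScanError(Exception):
    """Base class for all cementscan errors."""


class ValidationError(CementScanError, ValueError):
    """A precondition on user input was violated."""


class EmptyIntersectionError(ValidationError):
    """A requested slab does not intersect the volume."""


class EmptyRegionError(ValidationError):
    """A mask or region selects no (or too few) elements."""


class NoMetalError(ValidationError):
    """No prosthesis-range component large enough to be a tibial tray."""


class DegenerateGeometryError(ValidationError):
    """The metal component is not sheet-like; no tray plane can be fitted."""


class DepthOutOfProfileError(ValidationError):
    """A requested depth lies beyond the profiled depth range."""


class InfeasibleSpecError(ValidationError):
    """A phantom specification cannot be realised (e.g. tray thicker than volume)."""
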