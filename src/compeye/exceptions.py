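"""Exception hierarchy for the compound-eye pipeline."""


class CompeyeError(Exception):
    """Base class for all pipeline errors."""


class NoFocusableSurfaceError(CompeyeError):
    """Raised when a focus stack has no contrast anywhere (featureless)."""


class NoLatticeError(CompeyeError):
    """Raised when no periodic facet lattice is detectable in an image."""


class EmptyMapError(CompeyeError):
    """Raised when facet detection finds zero local maxima."""


class DegenerateGeometryError(CompeyeError):
    """Raised for coplanar point sets, underdetermined ellipses, etc."""


class InsufficientDataError(CompeyeError):
    """Raised when too few points/groups/flies are supplied for an analysis."""


class NormalizationError(CompeyeError):
    """Raised when a response group has a non-positive maximum."""


class ValidationError(CompeyeError):
    """Raised for malformed inputs (shape mismatches, bad metadata)."""
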