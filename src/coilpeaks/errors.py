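"""Exception hierarchy shared across the package."""


class CoilPeaksError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedResidueError(CoilPeaksError):
    """A residue type is absent from the dihedral library or anchor table."""


class UnsupportedAtomError(CoilPeaksError):
    """An atom was requested that the residue type does not carry (e.g. Gly CB)."""


class ConfigurationError(CoilPeaksError):
    """A constants table (library, anchors, windows) is missing or inconsistent."""


class DegenerateInputError(CoilPeaksError):
    """An input carries no usable signal (all-zero spectrum, empty ROI, ...)."""


class ValidationError(CoilPeaksError):
    """An argument violates a precondition (negative count, bad bounds, ...)."""


class MatchingError(CoilPeaksError):
    """Components above and below the diagonal could not be paired."""
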