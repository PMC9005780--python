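"""Exception and warning types raised across the toolkit."""


class AfmFibrilError(Exception):
    """Base class for all package errors."""


class FormatError(AfmFibrilError):
    """A file could not be parsed (malformed header, wrong format)."""


class UnsupportedGridError(AfmFibrilError):
    """Volumetric grid violates an assumption (e.g. anisotropic voxels)."""


class EmptySurfaceError(AfmFibrilError):
    """An operation removed or received all surface vertices."""


class AmbiguousAxisError(AfmFibrilError):
    """Point cloud too isotropic to define a unique long axis."""


class NoAxisFoundError(AfmFibrilError):
    """Screw-axis optimisation failed to reach a usable overlap."""


class TraceFailedError(AfmFibrilError):
    """Ridge following wandered off the fibril."""


class AperiodicProfileError(AfmFibrilError):
    """No significant non-DC peak in a centre-line height spectrum."""


class CoverageError(AfmFibrilError):
    """Angular coverage insufficient for envelope reconstruction."""


class GeometryError(AfmFibrilError):
    """Degenerate or self-intersecting planar geometry."""


class UndefinedScoreError(AfmFibrilError):
    """A similarity score is undefined (empty mask or zero variance)."""


class EstimationWarning(UserWarning):
    """A fitted parameter hit a search bound or otherwise looks unreliable."""


class BoundaryWarning(UserWarning):
    """An optimised parameter was clamped at the edge of its allowed interval."""


class AmbiguousSymmetryWarning(UserWarning):
    """Top two symmetry candidates score within the ambiguity margin."""


class NormalisationWarning(UserWarning):
    """All candidates share a parameter value; its distance is defined as 0."""
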