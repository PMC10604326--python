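"""Exception hierarchy shared by the whole pipeline.

Every domain failure derives from :class:`ProxhumError` so the CLI can map
library errors to exit code 1 while argument errors map to exit code 2.
"""


class ProxhumError(Exception):
    """Base class for all domain errors raised by proxhum."""


class MeshFormatError(ProxhumError):
    """A file could not be parsed as the named mesh format."""


class EmptyMeshError(ProxhumError):
    """An operation produced or received a mesh with no faces."""


class DegeneracyError(ProxhumError):
    """Input geometry is degenerate for the requested fit (coplanar points,
    spherical cloud for a cylinder fit, collinear landmarks, ...)."""


class ParameterError(ProxhumError):
    """A parameter violates its documented domain."""


class ConvergenceError(ProxhumError):
    """An iterative registration failed to reach a usable optimum."""


class WarpQualityError(ProxhumError):
    """Non-rigid warping failed to bring the template close to the target."""


class MeasurementError(ProxhumError):
    """An anatomical measurement could not be taken on the mesh."""


class DataError(ProxhumError):
    """Training or evaluation data are inconsistent (missing measurements,
    mismatched vertex counts, too few shapes)."""
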