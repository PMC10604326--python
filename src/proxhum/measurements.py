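"""The humeral coordinate system, the three geometric parameters, and ICC.

The bone-fixed frame follows the ISB-style construction: the origin is the
center of a sphere fitted to the articular surface of the humeral head, the
Y axis runs from the midpoint between the two distal epicondyles through
the head center (pointing proximally), the X axis is normal to the plane
spanned by the origin and the two caudal epicondylar points (pointing
laterally), and Z completes a right-handed triad.

Measured parameters (all mm): maximum humerus length (distance between the
two extreme planes normal to Y), humeral head radius (radius of the fitted
head sphere), and shaft circumference (perimeter of the cross-section cut
normal to Y at the level of the most protruding deltoid-tuberosity point,
i.e. halfway along the diaphysis).

Landmarks are template-defined and propagated through correspondence, which
removes the observer dependence of manual measuring; the intra-observer
reliability statistic (two-way ANOVA intraclass correlation, absolute
agreement, single measures) is still provided for replicated measurement
campaigns.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import shapely.geometry as sgeom

from .errors import DegeneracyError, MeasurementError, ParameterError
from .mesh_core import Plane, TriangleMesh, fit_sphere
from .synthetic import LandmarkIndex

MEASUREMENT_NAMES = ("max_length", "head_radius", "shaft_circumference")


@dataclasses.dataclass(frozen=True)
class HumeralCoordinateSystem:
    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=np.float64).reshape(3)
        axes = [np.asarray(a, dtype=np.float64).reshape(3)
                for a in (self.x_axis, self.y_axis, self.z_axis)]
        M = np.stack(axes)
        if np.abs(M @ M.T - np.eye(3)).max() > 1e-9:
            raise ParameterError("HCS axes must be orthonormal")
        if np.dot(np.cross(axes[0], axes[1]), axes[2]) < 0:
            raise ParameterError("HCS must be right-handed (x cross y = z)")
        object.__setattr__(self, "origin", o)
        for name, a in zip(("x_axis", "y_axis", "z_axis"), axes):
            object.__setattr__(self, name, a)


@dataclasses.dataclass(frozen=True)
class MeasurementSet:
    """The (optionally partial) set of conditioning measurements, in mm."""

    max_length: float | None = None
    head_radius: float | None = None
    shaft_circumference: float | None = None

    def __post_init__(self) -> None:
        for name in MEASUREMENT_NAMES:
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ParameterError(f"{name} must be positive if present")
        if (self.max_length is not None and self.head_radius is not None
                and not self.head_radius < self.max_length):
            raise ParameterError("head_radius must be smaller than max_length")

    def present(self) -> tuple[str, ...]:
        return tuple(n for n in MEASUREMENT_NAMES
                     if getattr(self, n) is not None)

    def as_dict(self) -> dict:
        return {n: getattr(self, n) for n in self.present()}

    def values_for(self, names) -> np.ndarray:
        out = []
        for n in names:
            v = getattr(self, n)
            if v is None:
                raise MeasurementError(f"measurement {n!r} is missing")
            out.append(float(v))
        return np.array(out)


# ---------------------------------------------------------------------------
# Coordinate system
# ---------------------------------------------------------------------------

def build_hcs(mesh: TriangleMesh, landmarks: LandmarkIndex) -> HumeralCoordinateSystem:
    v = mesh.vertices
    sphere = fit_sphere(v[landmarks.articular_surface])
    origin = sphere.center
    e_med = v[landmarks.epicondyle_medial_caudal].mean(axis=0)
    e_lat = v[landmarks.epicondyle_lateral_caudal].mean(axis=0)
    midpoint = 0.5 * (e_med + e_lat)
    y = origin - midpoint
    ny = np.linalg.norm(y)
    if ny < 1e-9:
        raise DegeneracyError("head center coincides with epicondyle midpoint")
    y = y / ny
    n = np.cross(e_med - origin, e_lat - origin)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        raise DegeneracyError("origin and epicondylar points are collinear")
    x = n / nn
    if np.dot(x, e_lat - e_med) < 0:  # orient laterally
        x = -x
    z = np.cross(x, y)
    z = z / np.linalg.norm(z)
    x = np.cross(y, z)  # re-orthogonalise; z is exactly perpendicular to y
    return HumeralCoordinateSystem(origin=origin, x_axis=x, y_axis=y, z_axis=z)


# ---------------------------------------------------------------------------
# The three parameters
# ---------------------------------------------------------------------------

def measure_max_length(mesh: TriangleMesh, hcs: HumeralCoordinateSystem) -> float:
    """Distance between the two extreme supporting planes normal to Y."""
    proj = mesh.vertices @ hcs.y_axis
    return float(proj.max() - proj.min())


def measure_head_radius(mesh: TriangleMesh, landmarks: LandmarkIndex) -> float:
    if landmarks.articular_surface.size == 0:
        raise MeasurementError("articular landmark set is empty")
    return fit_sphere(mesh.vertices[landmarks.articular_surface]).radius


def measure_shaft_circumference(mesh: TriangleMesh,
                                hcs: HumeralCoordinateSystem,
                                landmarks: LandmarkIndex) -> float:
    """Perimeter of the shaft cross-section at the deltoid-tuberosity level.

    The mesh is sectioned with the plane normal to Y through the deltoid
    landmark; among the resulting closed contours, the one enclosing the
    shaft axis is measured.
    """
    deltoid = mesh.vertices[landmarks.deltoid_tuberosity].mean(axis=0)
    level = float((deltoid - hcs.origin) @ hcs.y_axis)
    plane = Plane(point=hcs.origin + level * hcs.y_axis, normal=hcs.y_axis)
    section = mesh.to_trimesh().section(plane_origin=plane.point,
                                        plane_normal=plane.normal)
    if section is None:
        raise MeasurementError("section plane does not intersect the mesh")
    axis_point = plane.point  # Y axis pierces the shaft at this level
    b1 = hcs.x_axis
    b2 = hcs.z_axis
    target = sgeom.Point(0.0, 0.0)
    best = None
    for poly in section.discrete:
        uv = np.column_stack([(poly - plane.point) @ b1,
                              (poly - plane.point) @ b2])
        ring = sgeom.Polygon(uv)
        if ring.is_valid and ring.contains(target):
            length = float(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum())
            if best is None or length > best:
                best = length
    if best is None:
        raise MeasurementError(
            "no cross-section contour encloses the shaft axis "
            f"(point {axis_point})")
    return best


def measure_all(mesh: TriangleMesh, hcs: HumeralCoordinateSystem,
                landmarks: LandmarkIndex, which=MEASUREMENT_NAMES) -> MeasurementSet:
    which = tuple(which)
    if not which:
        raise ParameterError("requested measurement subset is empty")
    unknown = set(which) - set(MEASUREMENT_NAMES)
    if unknown:
        raise ParameterError(f"unknown measurements {sorted(unknown)}")
    values = {}
    if "max_length" in which:
        values["max_length"] = measure_max_length(mesh, hcs)
    if "head_radius" in which:
        values["head_radius"] = measure_head_radius(mesh, landmarks)
    if "shaft_circumference" in which:
        values["shaft_circumference"] = measure_shaft_circumference(
            mesh, hcs, landmarks)
    return MeasurementSet(**values)


# ---------------------------------------------------------------------------
# Intraclass correlation (two-way ANOVA, absolute agreement, single measures)
# ---------------------------------------------------------------------------

def icc(rep1, rep2) -> float:
    """ICC for two measurement sessions on the same subjects.

    Two-way mixed-effects, absolute-agreement, single-measure form,
    computed directly from the two-way ANOVA mean squares:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with n subjects and k = 2 sessions.  Returns a value in [-1, 1]; with
    zero between-subject variance the statistic is undefined and 0 is
    returned with a warning.
    """
    a = np.asarray(rep1, dtype=np.float64).ravel()
    b = np.asarray(rep2, dtype=np.float64).ravel()
    if a.size != b.size or a.size < 3:
        raise ParameterError("need two equal-length series of >= 3 subjects")
    data = np.column_stack([a, b])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-300 or msr < 1e-300:
        warnings.warn("zero between-subject variance; ICC undefined, "
                      "returning 0", stacklevel=2)
        return 0.0
    return float((msr - mse) / denom)
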