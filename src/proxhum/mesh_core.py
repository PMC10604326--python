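"""Triangle-mesh data model, file I/O and geometric primitives.

Everything downstream — the synthetic generator, registration, the shape
model and the deviation maps — moves :class:`TriangleMesh` objects around.
The type is a thin validated wrapper over ``(vertices, faces)`` arrays in
millimetres; heavy lifting (STL/PLY/OBJ parsing, plane slicing) is
delegated to :mod:`trimesh`.

Also provided here are the least-squares fits the anatomy work needs
(sphere to the articular surface, cylinder axis to the diaphysis) and an
exact closest-point-on-surface query used by registration and by the
deviation maps.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path as FsPath

import numpy as np
import trimesh
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .config import VERTEX_MERGE_TOL_MM
from .errors import (
    DegeneracyError,
    EmptyMeshError,
    MeshFormatError,
    ParameterError,
)

_FORMATS = {"stl", "ply", "obj"}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TriangleMesh:
    """A triangle surface mesh with coordinates in mm.

    Invariants enforced at construction: coordinates finite, face indices
    valid, more than 3 vertices and at least one face, and no zero-area
    faces (degenerate triangles are dropped silently — they carry no
    surface and would poison area-weighted statistics).
    """

    vertices: np.ndarray  # (N, 3) float64
    faces: np.ndarray     # (F, 3) int64

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise ParameterError(f"vertices must be (N, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ParameterError(f"faces must be (F, 3), got {f.shape}")
        if not np.all(np.isfinite(v)):
            raise ParameterError("vertices contain non-finite coordinates")
        if v.shape[0] <= 3:
            raise ParameterError(f"need more than 3 vertices, got {v.shape[0]}")
        if f.size and (f.min() < 0 or f.max() >= v.shape[0]):
            raise ParameterError("face indices out of range")
        # drop zero-area faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        area2 = np.linalg.norm(cross, axis=1)
        keep = area2 > 1e-12
        f = f[keep]
        if f.shape[0] == 0:
            raise EmptyMeshError("mesh has no non-degenerate faces")
        v.setflags(write=False)
        f.setflags(write=False)
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    # -- conversions -------------------------------------------------------

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=np.array(self.vertices), faces=np.array(self.faces),
            process=False,
        )

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "TriangleMesh":
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces))

    # -- derived quantities ------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def face_areas(self) -> np.ndarray:
        v, f = self.vertices, self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def face_normals(self) -> np.ndarray:
        v, f = self.vertices, self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        n = np.linalg.norm(cross, axis=1, keepdims=True)
        return cross / np.maximum(n, 1e-300)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def vertex_areas(self) -> np.ndarray:
        """Barycentric area weights: one third of each incident triangle."""
        fa = self.face_areas()
        w = np.zeros(self.n_vertices)
        np.add.at(w, self.faces.ravel(), np.repeat(fa / 3.0, 3))
        return w

    def vertex_normals(self) -> np.ndarray:
        fn = self.face_normals() * self.face_areas()[:, None]
        vn = np.zeros_like(self.vertices)
        np.add.at(vn, self.faces.ravel(), np.repeat(fn, 3, axis=0))
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        return vn / np.maximum(norm, 1e-300)

    def edges_unique(self) -> np.ndarray:
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        """Same topology, new vertex positions."""
        return TriangleMesh(vertices, self.faces)


@dataclasses.dataclass(frozen=True)
class Plane:
    """An oriented plane: a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.point, dtype=np.float64).reshape(3)
        n = np.asarray(self.normal, dtype=np.float64).reshape(3)
        nn = np.linalg.norm(n)
        if nn < 1e-12:
            raise ParameterError("plane normal must be non-zero")
        n = n / nn
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) - self.point) @ self.normal


@dataclasses.dataclass(frozen=True)
class SphereFit:
    center: np.ndarray
    radius: float
    rms_residual: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center",
                           np.asarray(self.center, dtype=np.float64).reshape(3))
        if not self.radius > 0:
            raise DegeneracyError(f"non-positive sphere radius {self.radius}")
        if self.rms_residual < 0:
            raise ParameterError("rms_residual must be >= 0")


@dataclasses.dataclass(frozen=True)
class AxisFit:
    point: np.ndarray
    direction: np.ndarray
    rms_residual: float

    def __post_init__(self) -> None:
        p = np.asarray(self.point, dtype=np.float64).reshape(3)
        d = np.asarray(self.direction, dtype=np.float64).reshape(3)
        nd = np.linalg.norm(d)
        if abs(nd - 1.0) > 1e-9:
            d = d / nd
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "direction", d)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _infer_format(path: FsPath, fmt: str | None) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise ParameterError(f"unsupported mesh format {fmt!r}; use one of {sorted(_FORMATS)}")
    return fmt


def read_mesh(path, fmt: str | None = None) -> TriangleMesh:
    """Read an STL (binary or ASCII), PLY or OBJ file.

    Duplicate vertices within ``VERTEX_MERGE_TOL_MM`` are merged so that
    faces share vertices — STL stores each facet independently and the
    correspondence bookkeeping downstream requires shared vertices.
    """
    path = FsPath(path)
    fmt = _infer_format(path, fmt)
    if not path.exists():
        raise IOError(f"mesh file does not exist: {path}")
    try:
        tm = trimesh.load(str(path), file_type=fmt, process=False)
    except Exception as exc:  # noqa: BLE001 - normalise loader errors
        raise MeshFormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise MeshFormatError(f"{path} does not contain a triangle mesh")
    tm.merge_vertices(merge_tex=True, merge_norm=True,
                      digits_vertex=int(-np.log10(VERTEX_MERGE_TOL_MM)))
    return TriangleMesh.from_trimesh(tm)


def write_mesh(mesh: TriangleMesh, path, fmt: str | None = None) -> None:
    """Write a mesh readable by :func:`read_mesh` and standard viewers."""
    path = FsPath(path)
    fmt = _infer_format(path, fmt)
    # ASCII STL keeps full float precision (binary STL is float32)
    export_type = "stl_ascii" if fmt == "stl" else fmt
    try:
        mesh.to_trimesh().export(str(path), file_type=export_type)
    except OSError as exc:
        raise IOError(f"could not write mesh to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Elementary measures and transforms
# ---------------------------------------------------------------------------

def mean_edge_length(mesh: TriangleMesh) -> float:
    """Arithmetic mean length over unique edges (mm)."""
    e = mesh.edges_unique()
    d = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    return float(d.mean())


def mirror_mesh(mesh: TriangleMesh, plane: Plane) -> TriangleMesh:
    """Reflect across a plane; winding is flipped so outward normals survive."""
    d = plane.signed_distance(mesh.vertices)
    v = mesh.vertices - 2.0 * d[:, None] * plane.normal
    f = mesh.faces[:, ::-1]
    return TriangleMesh(v, f)


def cut_mesh_by_plane(mesh: TriangleMesh, plane: Plane, keep: str = "positive") -> TriangleMesh:
    """Keep the part of the mesh in one closed half-space of the plane.

    Triangles straddling the plane are split at the intersection.  The cut
    boundary is left as an open polyline — no cap is added, because the
    deviation evaluation compares surfaces and a cap would contribute
    spurious area.
    """
    if keep not in ("positive", "negative"):
        raise ParameterError(f"keep must be 'positive' or 'negative', got {keep!r}")
    normal = plane.normal if keep == "positive" else -plane.normal
    sliced = trimesh.intersections.slice_mesh_plane(
        mesh.to_trimesh(), plane_normal=normal, plane_origin=plane.point, cap=False,
    )
    if sliced is None or len(sliced.faces) == 0:
        raise EmptyMeshError("plane cut discarded the entire mesh")
    return TriangleMesh.from_trimesh(sliced)


# ---------------------------------------------------------------------------
# Least-squares fits
# ---------------------------------------------------------------------------

def fit_sphere(points: np.ndarray) -> SphereFit:
    """Least-squares sphere through a point cloud.

    Algebraic (Kasa) linear solve followed by one geometric Gauss-Newton
    refinement pass on (center, radius).
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 4:
        raise DegeneracyError("sphere fit needs >= 4 points")
    # rank check: points must not be coplanar
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] < 1e-9 * max(sv[0], 1.0):
        raise DegeneracyError("points are (nearly) coplanar; sphere fit is degenerate")
    # Kasa: |x|^2 = 2 c.x + (r^2 - |c|^2)
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = (pts ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(max(sol[3] + center @ center, 1e-300)))

    # one geometric refinement pass (Gauss-Newton on r_i - r)
    def residual(p):
        c, r = p[:3], p[3]
        return np.linalg.norm(pts - c, axis=1) - r

    res = least_squares(residual, np.r_[center, radius], method="lm", max_nfev=20)
    center, radius = res.x[:3], float(res.x[3])
    rms = float(np.sqrt(np.mean(residual(res.x) ** 2)))
    return SphereFit(center=center, radius=radius, rms_residual=rms)


def fit_cylinder_axis(points: np.ndarray) -> AxisFit:
    """Axis of the best-fit cylinder through a point cloud.

    Minimises the variance of radial distances about the axis.  The
    covariance eigenvectors seed the direction (both the largest- and the
    smallest-spread directions are tried, to cover long tubes and flat
    rings alike) and a nonlinear least-squares pass refines it.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 6:
        raise DegeneracyError("cylinder-axis fit needs >= 6 points")
    mean = pts.mean(axis=0)
    centered = pts - mean
    _, _, vt = np.linalg.svd(centered, full_matrices=False)

    def radial(dir_vec, c_par):
        d = dir_vec / np.linalg.norm(dir_vec)
        # point on axis = mean + offset perpendicular to d
        b1, b2 = _plane_basis(d)
        offset = c_par[0] * b1 + c_par[1] * b2
        rel = centered - offset
        perp = rel - np.outer(rel @ d, d)
        return np.linalg.norm(perp, axis=1)

    def refine(d0):
        b1, b2 = _plane_basis(d0)

        def unpack(p):
            # direction parametrised by two tilt angles about the seed
            d = d0 + p[0] * b1 + p[1] * b2
            return d / np.linalg.norm(d), p[2:4]

        def residual(p):
            d, off = unpack(p)
            r = radial(d, off)
            return r - r.mean()

        res = least_squares(residual, np.zeros(4), method="lm", max_nfev=200)
        d, off = unpack(res.x)
        r = radial(d, off)
        rms = float(np.sqrt(np.mean((r - r.mean()) ** 2)))
        return d, off, rms

    best = None
    for seed_dir in (vt[0], vt[2]):
        d, off, rms = refine(seed_dir)
        if best is None or rms < best[2]:
            best = (d, off, rms)
    d, off, rms = best
    r = radial(d, off)
    if r.mean() < 1e-9 or rms > 0.2 * r.mean():
        raise DegeneracyError(
            f"point cloud has no cylindrical structure (radial rms {rms:.3g} "
            f"vs mean radius {r.mean():.3g})")
    b1, b2 = _plane_basis(d)
    point = mean + off[0] * b1 + off[1] * b2
    # canonical orientation: positive projection on the dominant component
    if d @ vt[0] < 0:
        d = -d
    return AxisFit(point=point, direction=d, rms_residual=rms)


def _plane_basis(n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane orthogonal to n."""
    n = n / np.linalg.norm(n)
    a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    b1 = np.cross(n, a)
    b1 /= np.linalg.norm(b1)
    b2 = np.cross(n, b1)
    return b1, b2


# ---------------------------------------------------------------------------
# Closest-point queries
# ---------------------------------------------------------------------------

class SurfaceQuery:
    """Exact closest-point-on-surface queries against one mesh.

    Candidate triangles come from a KD-tree over triangle centroids
    (k nearest centroids per query point, with k scaled to the mesh); the
    exact point-triangle distance is then evaluated on the candidates.
    Ties are broken toward the lowest face index, which makes every
    downstream pipeline deterministic.
    """

    def __init__(self, mesh: TriangleMesh, k: int = 16):
        self.mesh = mesh
        tri = mesh.vertices[mesh.faces]
        self._tri = tri
        self._centroids = tri.mean(axis=1)
        # candidate search must not miss the true nearest triangle: pad k by
        # the largest triangle circumradius via a conservative radius bump
        self._tree = cKDTree(self._centroids)
        self._k = min(k, mesh.n_faces)
        self._face_normals = mesh.face_normals()

    def query(self, points: np.ndarray):
        """Return (closest_points, distances, face_indices) for each point."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        _, cand = self._tree.query(pts, k=self._k)
        cand = np.atleast_2d(cand)
        cand.sort(axis=1)  # ascending face index -> argmin tie-break = lowest
        closest = _closest_point_on_triangles(pts, self._tri, cand)
        d2 = ((closest - pts[:, None, :]) ** 2).sum(axis=2)
        best = d2.argmin(axis=1)
        rows = np.arange(len(pts))
        cp = closest[rows, best]
        faces = cand[rows, best]
        dist = np.sqrt(d2[rows, best])
        return cp, dist, faces

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Distance signed by the closest face's outward normal:
        positive = the query point lies outside this surface."""
        cp, dist, faces = self.query(points)
        sign = np.sign(np.einsum("ij,ij->i", np.atleast_2d(points) - cp,
                                 self._face_normals[faces]))
        sign[sign == 0] = 1.0
        return sign * dist


def _closest_point_on_triangles(pts: np.ndarray, tri: np.ndarray,
                                cand: np.ndarray) -> np.ndarray:
    """Closest point on each candidate triangle for each query point.

    Vectorised region-based projection (Ericson, Real-Time Collision
    Detection, 5.1.5).  ``pts`` is (P,3), ``cand`` is (P,K) face indices;
    returns (P,K,3).
    """
    a = tri[cand, 0]
    b = tri[cand, 1]
    c = tri[cand, 2]
    p = pts[:, None, :]

    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("pkd,pkd->pk", ab, ap)
    d2 = np.einsum("pkd,pkd->pk", ac, ap)

    bp = p - b
    d3 = np.einsum("pkd,pkd->pk", ab, bp)
    d4 = np.einsum("pkd,pkd->pk", ac, bp)

    cp_ = p - c
    d5 = np.einsum("pkd,pkd->pk", ab, cp_)
    d6 = np.einsum("pkd,pkd->pk", ac, cp_)

    out = np.empty_like(a)
    done = np.zeros(a.shape[:2], dtype=bool)

    def assign(mask, value):
        m = mask & ~done
        out[m] = value[m]
        done[m] = True

    assign((d1 <= 0) & (d2 <= 0), a)                       # vertex A
    assign((d3 >= 0) & (d4 <= d3), b)                      # vertex B
    assign((d6 >= 0) & (d5 <= d6), c)                      # vertex C

    vc = d1 * d4 - d3 * d2
    v_ab = np.where(np.abs(d1 - d3) > 0, d1 / np.where(d1 - d3 == 0, 1, d1 - d3), 0)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[..., None] * ab)  # edge AB

    vb = d5 * d2 - d1 * d6
    w_ac = np.where(np.abs(d2 - d6) > 0, d2 / np.where(d2 - d6 == 0, 1, d2 - d6), 0)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[..., None] * ac)  # edge AC

    va = d3 * d6 - d5 * d4
    denom_bc = (d4 - d3) + (d5 - d6)
    w_bc = np.where(denom_bc != 0, (d4 - d3) / np.where(denom_bc == 0, 1, denom_bc), 0)
    assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
           b + w_bc[..., None] * (c - b))                  # edge BC

    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v = vb / denom
    w = vc / denom
    assign(np.ones_like(done), a + v[..., None] * ab + w[..., None] * ac)  # interior
    return out
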