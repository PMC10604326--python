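"""Rigid and non-rigid registration: ICP, Procrustes alignment, warping.

Dense correspondence across a bone population is established by warping a
reference mesh onto every target surface so all shapes share one topology;
pose differences are then removed by rigid alignment only — no scaling, so
size remains a modelled shape variable.  Manual pre-alignment of clinical
workflows is replaced by an automatic centroid + principal-axes
initialisation with the four axis-sign disambiguations resolved by matched
distance.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import DEFAULT_STIFFNESS_SCHEDULE
from .errors import ConvergenceError, DataError, ParameterError, WarpQualityError
from .mesh_core import SurfaceQuery, TriangleMesh


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion x -> R x + t (rotation + translation, no
    scaling, no reflection)."""

    rotation: np.ndarray    # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-9:
            raise ParameterError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ParameterError("rotation must have determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def apply_mesh(self, mesh: TriangleMesh) -> TriangleMesh:
        return mesh.with_vertices(self.apply(mesh.vertices))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclasses.dataclass
class CorrespondedShapeSet:
    """M shapes sharing one triangulation: the input of the shape model.

    ``shapes`` is (M, N, 3); vertex i means the same anatomical locus in
    every shape.
    """

    faces: np.ndarray           # (F, 3)
    shapes: np.ndarray          # (M, N, 3)
    labels: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.shapes = np.asarray(self.shapes, dtype=np.float64)
        if self.shapes.ndim != 3 or self.shapes.shape[2] != 3:
            raise DataError(f"shapes must be (M, N, 3), got {self.shapes.shape}")
        n = self.shapes.shape[1]
        if n < 4:
            raise DataError("shapes need at least 4 vertices")
        if self.faces.size and self.faces.max() >= n:
            raise DataError("faces reference vertices beyond shape size")
        if not self.labels:
            self.labels = [f"shape_{i}" for i in range(self.n_shapes)]
        if len(self.labels) != self.n_shapes:
            raise DataError("one label per shape required")

    @property
    def n_shapes(self) -> int:
        return self.shapes.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.shapes.shape[1]

    def mesh(self, i: int) -> TriangleMesh:
        return TriangleMesh(self.shapes[i], self.faces)


# ---------------------------------------------------------------------------
# Kabsch / rigid ICP
# ---------------------------------------------------------------------------

def kabsch(source: np.ndarray, target: np.ndarray,
           weights: np.ndarray | None = None) -> RigidTransform:
    """Least-squares proper rigid transform mapping corresponded ``source``
    points onto ``target`` (SVD solution; reflection explicitly excluded)."""
    P = np.asarray(source, dtype=np.float64)
    Q = np.asarray(target, dtype=np.float64)
    if weights is None:
        w = np.full(len(P), 1.0 / len(P))
    else:
        w = np.asarray(weights, dtype=np.float64)
        w = w / w.sum()
    cp = w @ P
    cq = w @ Q
    H = (P - cp).T @ ((Q - cq) * w[:, None])
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cq - R @ cp
    return RigidTransform(R, t)


def _principal_frame(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c, full_matrices=False)
    if np.linalg.det(vt) < 0:  # canonical right-handed frame
        vt = vt.copy()
        vt[2] = -vt[2]
    return c, vt  # rows = principal directions, descending spread


def _prealign_candidates(source: TriangleMesh, target: TriangleMesh):
    """Centroid + principal-axes alignments; four sign flips keep det +1."""
    cs, vs = _principal_frame(source.vertices)
    ct, vt = _principal_frame(target.vertices)
    for s1, s2 in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        signs = np.array([s1, s2, s1 * s2], dtype=float)
        R = vt.T @ np.diag(signs) @ vs
        if np.linalg.det(R) < 0:  # defensive; signs chosen to keep det +1
            continue
        yield RigidTransform(R, ct - R @ cs)


def icp_rigid(source: TriangleMesh, target: TriangleMesh,
              max_iter: int = 60, tol: float = 1e-4,
              pre_align: bool = True) -> RigidTransform:
    """Rigid ICP of ``source`` onto ``target`` (scale fixed at 1).

    Matches every source vertex to its closest point on the target surface,
    solves the Kabsch transform, and repeats until the mean-squared matched
    distance improves by less than ``tol**2`` or ``max_iter`` is reached.
    Returns the accumulated transform; its rotation always has det +1, so a
    mirrored input is never silently absorbed.
    """
    query = SurfaceQuery(target)
    src0 = source.vertices
    # deterministic subsample for candidate scoring
    step = max(1, src0.shape[0] // 400)
    probe = src0[::step]

    if pre_align:
        best, best_d = None, np.inf
        for cand in _prealign_candidates(source, target):
            _, d, _ = query.query(cand.apply(probe))
            md = float(np.mean(d ** 2))
            if md < best_d:
                best, best_d = cand, md
        transform = best
    else:
        transform = RigidTransform.identity()

    prev_mse = np.inf
    for _ in range(max_iter):
        moved = transform.apply(src0)
        cp, d, _ = query.query(moved)
        mse = float(np.mean(d ** 2))
        if prev_mse - mse < tol ** 2:
            break
        prev_mse = mse
        step_tf = kabsch(moved, cp)
        transform = step_tf.compose(transform)

    moved = transform.apply(src0)
    _, d, _ = query.query(moved)
    diag = float(np.linalg.norm(target.vertices.max(0) - target.vertices.min(0)))
    if float(np.mean(d)) > diag:
        raise ConvergenceError(
            f"ICP failed: mean matched distance {np.mean(d):.1f} mm exceeds "
            f"target bounding-box diagonal {diag:.1f} mm")
    return transform


# ---------------------------------------------------------------------------
# Generalized Procrustes (rotations + translations only)
# ---------------------------------------------------------------------------

def align_set(shapes: CorrespondedShapeSet, tol: float = 1e-6,
              max_iter: int = 100) -> CorrespondedShapeSet:
    """Generalised Procrustes alignment without scaling.

    Iteratively aligns every shape to the current mean with the
    corresponded-points Kabsch solution and recomputes the mean, until the
    mean moves by less than ``tol`` mm.  The output mean is centred at the
    origin; size differences between shapes are preserved.
    """
    X = shapes.shapes.copy()
    mean = X[0] - X[0].mean(axis=0)
    for _ in range(max_iter):
        for i in range(X.shape[0]):
            X[i] = kabsch(X[i], mean).apply(X[i])
        new_mean = X.mean(axis=0)
        new_mean = new_mean - new_mean.mean(axis=0)
        move = float(np.abs(new_mean - mean).max())
        mean = new_mean
        if move < tol:
            break
    # final pass against the converged mean so every shape is aligned to it
    for i in range(X.shape[0]):
        X[i] = kabsch(X[i], mean).apply(X[i])
    return CorrespondedShapeSet(faces=shapes.faces, shapes=X,
                                labels=list(shapes.labels))


def procrustes_variance(shapes: CorrespondedShapeSet) -> float:
    """Total variance about the Procrustes mean (mm^2)."""
    mean = shapes.shapes.mean(axis=0)
    return float(((shapes.shapes - mean) ** 2).sum() / shapes.n_shapes)


# ---------------------------------------------------------------------------
# Non-rigid template warping
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class WarpReport:
    p99_surface_distance: float
    mean_surface_distance: float
    stiffness_schedule: tuple[float, ...]


#: Weight of the point-to-point stabiliser relative to the point-to-plane
#: data term in the non-rigid warp.
_WARP_POINT_WEIGHT = 0.05


def warp_template(template: TriangleMesh, target: TriangleMesh,
                  stiffness_schedule=DEFAULT_STIFFNESS_SCHEDULE,
                  inner_iterations: int = 10,
                  return_report: bool = False):
    """Deform the template onto the target surface, keeping its topology.

    Laplacian-regularised non-rigid ICP: at each stiffness level ``alpha``
    the per-vertex displacement field ``D`` solves the sparse linear
    least-squares problem

        min  sum_i  [ ((v_i + d_i - c_i) . n_i)^2  +  beta ||v_i + d_i - c_i||^2 ]
             + alpha * sum_edges ||d_i - d_j||^2

    where ``c_i`` is the current closest point on the target and ``n_i``
    the normal of its triangle.  The point-to-plane data term leaves
    tangential motion free, so the stiffness term can distribute stretch
    smoothly along featureless regions (a cylindrical shaft, the spherical
    head); the small point-to-point weight ``beta`` keeps the system well
    posed.  The schedule runs coarse-to-fine so global shape differences
    are absorbed before local detail is fitted.  Inputs should be roughly
    aligned (run :func:`icp_rigid` first).
    """
    sched = tuple(float(s) for s in stiffness_schedule)
    if any(s <= 0 for s in sched) or any(b >= a for a, b in zip(sched, sched[1:])):
        raise ParameterError("stiffness schedule must be positive and decreasing")

    V0 = template.vertices
    n = template.n_vertices
    edges = template.edges_unique()
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    adj = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    lap = (sp.diags(np.asarray(adj.sum(axis=1)).ravel()) - adj).tocsr()
    lap3 = sp.kron(lap, sp.identity(3), format="csc")

    query = SurfaceQuery(target)
    face_normals = target.face_normals()
    eye3 = np.eye(3)
    diag_ptr = np.arange(n + 1)
    D = np.zeros_like(V0)
    for alpha in sched:
        for _ in range(inner_iterations):
            cp, _, faces = query.query(V0 + D)
            nrm = face_normals[faces]
            blocks = (nrm[:, :, None] * nrm[:, None, :]
                      + _WARP_POINT_WEIGHT * eye3[None])
            data = sp.bsr_matrix((blocks, np.arange(n), diag_ptr),
                                 shape=(3 * n, 3 * n)).tocsc()
            rhs = np.einsum("ijk,ik->ij", blocks, cp - V0).ravel()
            D = spla.spsolve(data + alpha * lap3, rhs).reshape(n, 3)

    warped = template.with_vertices(V0 + D)
    _, dist, _ = query.query(warped.vertices)
    from .mesh_core import mean_edge_length  # local import to avoid cycle noise
    mel = mean_edge_length(template)
    if float(dist.mean()) > 10.0 * mel:
        raise WarpQualityError(
            f"warp failed to approach target: mean surface distance "
            f"{dist.mean():.2f} mm vs template mean edge {mel:.2f} mm")
    if return_report:
        report = WarpReport(p99_surface_distance=float(np.percentile(dist, 99)),
                            mean_surface_distance=float(dist.mean()),
                            stiffness_schedule=sched)
        return warped, report
    return warped
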