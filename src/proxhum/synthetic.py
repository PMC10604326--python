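"""Parametric synthetic humerus populations with known ground truth.

Clinical CT cohorts cannot be redistributed, so every stage of the pipeline
is validated on generated humerus-like meshes whose latent anatomy is known
exactly.  A bone is described by seven latent factors — maximum length,
humeral head radius, shaft radius, neck-shaft angle, medial head offset,
deltoid-tuberosity prominence and epicondylar width — and realised on a
fixed parametric grid:

* a generalized cylinder around the long (z) axis forms the diaphysis and
  the distal end, with radius bumps for the two epicondyles, the trochlea
  and the deltoid tuberosity, and an elliptic closure at the distal pole;
* a spherical cap of the head radius, tilted by the neck-shaft angle and
  offset medially, forms the articular surface, joined to the shaft by a
  linearly blended neck band.

Because every instance is evaluated on the same (row, angle) grid, vertex i
refers to the same anatomical locus in every mesh: dense correspondence
holds by construction, landmark vertex sets are known exactly, and the
latent-to-shape map is (near-)linear so a noiseless population driven by k
latent factors has essentially rank-k shape covariance.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import ParameterError
from .mesh_core import Plane, TriangleMesh, mirror_mesh
from .registration import CorrespondedShapeSet

LATENT_FIELDS = (
    "length", "head_radius", "shaft_radius", "neck_shaft_angle",
    "head_offset", "deltoid_prominence", "epicondyle_width",
)

#: Rim half-angle of the articular spherical cap (radians).
_CAP_OMEGA = np.deg2rad(105.0)

# normalized stations of the radius-field features (fractions of shaft span)
_T_CLOSE = 0.03     # distal elliptic closure
_T_EPI = 0.055      # epicondylar level
_T_TROCHLEA = 0.03
_T_DELTOID = 0.50   # mid-diaphysis
_THETA_MEDIAL = 0.0
_THETA_LATERAL = np.pi
_THETA_TROCHLEA = 1.5 * np.pi


@dataclasses.dataclass(frozen=True)
class HumerusLatent:
    """Latent anatomical factors of one synthetic humerus (mm / degrees)."""

    length: float = 310.0
    head_radius: float = 24.0
    shaft_radius: float = 10.0
    neck_shaft_angle: float = 135.0
    head_offset: float = 6.0
    deltoid_prominence: float = 2.0
    epicondyle_width: float = 60.0

    def __post_init__(self) -> None:
        for f in ("length", "head_radius", "shaft_radius", "head_offset",
                  "deltoid_prominence", "epicondyle_width"):
            if getattr(self, f) <= 0:
                raise ParameterError(f"{f} must be positive")
        if not self.head_radius < self.length / 4:
            raise ParameterError("head_radius must be < length / 4")
        if not self.shaft_radius < self.head_radius:
            raise ParameterError("shaft_radius must be < head_radius")
        if not 110.0 < self.neck_shaft_angle < 160.0:
            raise ParameterError("neck_shaft_angle must lie in (110, 160) degrees")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in LATENT_FIELDS])

    @classmethod
    def from_array(cls, a) -> "HumerusLatent":
        return cls(**dict(zip(LATENT_FIELDS, (float(x) for x in a))))

    def replace(self, **kw) -> "HumerusLatent":
        return dataclasses.replace(self, **kw)


#: Default population spread (one standard deviation per latent field),
#: chosen to emulate healthy adult variation at realistic magnitudes.
DEFAULT_LATENT_SDS = {
    "length": 18.0,
    "head_radius": 1.8,
    "shaft_radius": 1.0,
    "neck_shaft_angle": 5.0,
    "head_offset": 1.0,
    "deltoid_prominence": 0.5,
    "epicondyle_width": 3.5,
}


@dataclasses.dataclass(frozen=True)
class PopulationSpec:
    """Sampling recipe for a synthetic cohort."""

    n: int
    latent_means: HumerusLatent = HumerusLatent()
    latent_sds: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_LATENT_SDS))
    seed: int = 0
    template_resolution: float = 1.5

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ParameterError("population needs n >= 2")
        if any(v < 0 for v in self.latent_sds.values()):
            raise ParameterError("latent sds must be >= 0")
        unknown = set(self.latent_sds) - set(LATENT_FIELDS)
        if unknown:
            raise ParameterError(f"unknown latent fields {sorted(unknown)}")
        if not 0.5 <= self.template_resolution <= 5.0:
            raise ParameterError("template_resolution must be in [0.5, 5] mm")


@dataclasses.dataclass(frozen=True)
class LandmarkIndex:
    """Named vertex-index sets on the template topology."""

    articular_surface: np.ndarray
    epicondyle_medial_caudal: np.ndarray
    epicondyle_lateral_caudal: np.ndarray
    trochlea_inferior: np.ndarray
    head_superior: np.ndarray
    deltoid_tuberosity: np.ndarray

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            arr = np.asarray(getattr(self, f.name), dtype=np.int64).ravel()
            if arr.size == 0:
                raise ParameterError(f"landmark set {f.name} is empty")
            object.__setattr__(self, f.name, arr)

    def to_dict(self) -> dict:
        return {f.name: np.asarray(getattr(self, f.name)).tolist()
                for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkIndex":
        return cls(**{k: np.asarray(v, dtype=np.int64) for k, v in d.items()})


@dataclasses.dataclass(frozen=True)
class _GridSpec:
    """Frozen discretisation: same grid -> correspondence by construction."""

    n_theta: int
    tube_t: np.ndarray      # normalized stations in (0, 1]
    n_neck: int             # blend rows between shaft top and cap rim
    cap_phi: np.ndarray     # polar angles from the rim toward the apex
    resolution: float


@dataclasses.dataclass(frozen=True)
class HumerusTemplate:
    mesh: TriangleMesh
    landmarks: LandmarkIndex
    grid: _GridSpec
    latent: HumerusLatent


# ---------------------------------------------------------------------------
# Radius field of the tube part (linear in the length-like latents)
# ---------------------------------------------------------------------------

def _ang_dist(theta, theta0):
    d = np.abs((theta - theta0 + np.pi) % (2 * np.pi) - np.pi)
    return d


def _base_profile(t):
    """Dimensionless shaft profile: distal flare, constant shaft, neck flare."""
    return (1.0
            + 0.6 * np.exp(-((t / 0.08) ** 2))
            + 0.25 * np.exp(-(((1.0 - t) / 0.06) ** 2)))


def _radius_field(t, theta, latent: HumerusLatent):
    """Cross-section radius r(t, theta) of the tube part, in mm."""
    s = latent.shaft_radius
    base = s * _base_profile(t)
    # epicondylar bulges (medial + lateral) sized so the full width across
    # the epicondylar level equals epicondyle_width
    a_epi = latent.epicondyle_width / 2.0 - s * _base_profile(_T_EPI)
    g_t = np.exp(-((t - _T_EPI) ** 2) / (2 * 0.035 ** 2))
    g_th = (np.exp(-(_ang_dist(theta, _THETA_MEDIAL) ** 2) / (2 * 0.55 ** 2))
            + np.exp(-(_ang_dist(theta, _THETA_LATERAL) ** 2) / (2 * 0.55 ** 2)))
    r = base + a_epi * g_t * g_th
    # trochlear prominence (anterior-distal)
    r = r + 0.35 * s * (np.exp(-((t - _T_TROCHLEA) ** 2) / (2 * 0.02 ** 2))
                        * np.exp(-(_ang_dist(theta, _THETA_TROCHLEA) ** 2)
                                 / (2 * 0.5 ** 2)))
    # deltoid tuberosity (lateral, mid-diaphysis)
    r = r + latent.deltoid_prominence * (
        np.exp(-((t - _T_DELTOID) ** 2) / (2 * 0.04 ** 2))
        * np.exp(-(_ang_dist(theta, _THETA_LATERAL) ** 2) / (2 * 0.7 ** 2)))
    # elliptic closure toward the distal pole
    env = np.ones_like(np.asarray(t, dtype=float))
    close = t < _T_CLOSE
    env = np.where(close,
                   np.sqrt(np.clip(1.0 - ((_T_CLOSE - t) / _T_CLOSE) ** 2, 0.0, 1.0)),
                   env)
    return env * r


def _head_frame(latent: HumerusLatent):
    """Head center, head axis and rim basis (medial tilt of the neck)."""
    tau = np.deg2rad(180.0 - latent.neck_shaft_angle)
    u = np.array([np.sin(tau), 0.0, np.cos(tau)])
    center = np.array([latent.head_offset, 0.0,
                       latent.length - latent.head_radius])
    e1 = np.array([1.0, 0.0, 0.0]) - u[0] * u
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return center, u, e1, e2


def _shaft_top_z(latent: HumerusLatent) -> float:
    return latent.length - 2.6 * latent.head_radius


# ---------------------------------------------------------------------------
# Grid construction and surface evaluation
# ---------------------------------------------------------------------------

def _make_grid(resolution: float, latent: HumerusLatent) -> _GridSpec:
    if not 0.5 <= resolution <= 5.0:
        raise ParameterError("resolution must be in [0.5, 5] mm")
    # angular resolution sized for an effective radius between shaft and head
    r_eff = 1.35 * latent.shaft_radius
    n_theta = max(12, 2 * int(round(np.pi * r_eff / resolution)))
    z_neck = _shaft_top_z(latent)
    # distal closure rows: uniform meridian arc steps over the elliptic cap
    r_distal = latent.shaft_radius * _base_profile(0.0)
    n_close = max(3, int(np.ceil(r_distal * (np.pi / 2) / resolution)))
    psi = np.linspace(0.0, np.pi / 2, n_close + 1)[1:]
    t_close = _T_CLOSE * (1.0 - np.cos(psi))
    # uniform stations above the closure
    n_tube = max(4, int(np.ceil((1.0 - _T_CLOSE) * z_neck / resolution)))
    t_tube = np.linspace(_T_CLOSE, 1.0, n_tube + 1)[1:]
    tube_t = np.concatenate([t_close, t_tube])
    # neck band rows sized on the default gap between shaft top and rim
    n_neck = max(2, int(np.ceil(0.85 * latent.head_radius / resolution)))
    # cap rows: uniform polar steps from the rim to near the apex
    n_cap = max(3, int(np.ceil(latent.head_radius * _CAP_OMEGA / resolution)))
    cap_phi = np.linspace(_CAP_OMEGA, 0.0, n_cap + 1)[:-1]
    return _GridSpec(n_theta=n_theta, tube_t=tube_t, n_neck=n_neck,
                     cap_phi=cap_phi, resolution=resolution)


def _evaluate(grid: _GridSpec, latent: HumerusLatent):
    """Vertices, faces and landmark sets of one latent on the fixed grid."""
    nth = grid.n_theta
    theta = np.arange(nth) * (2 * np.pi / nth)
    z_neck = _shaft_top_z(latent)
    center, u, e1, e2 = _head_frame(latent)
    R = latent.head_radius

    rows = []
    # tube rows
    for t in grid.tube_t:
        r = _radius_field(np.full(nth, t), theta, latent)
        rows.append(np.column_stack([r * np.cos(theta), r * np.sin(theta),
                                     np.full(nth, t * z_neck)]))
    shaft_top = rows[-1]
    # cap rim ring (first articular ring)
    def cap_ring(phi):
        d = (np.cos(phi) * u[None, :]
             + np.sin(phi) * (np.cos(theta)[:, None] * e1[None, :]
                              + np.sin(theta)[:, None] * e2[None, :]))
        return center[None, :] + R * d

    rim = cap_ring(grid.cap_phi[0])
    # neck blend rows between shaft top and rim (exclusive endpoints)
    for k in range(1, grid.n_neck):
        lam = k / grid.n_neck
        rows.append((1.0 - lam) * shaft_top + lam * rim)
    cap_row_start = len(rows)
    for phi in grid.cap_phi:
        rows.append(cap_ring(phi))

    n_rows = len(rows)
    verts = np.concatenate(
        [np.zeros((1, 3)),                    # distal pole (trochlea inferior)
         np.concatenate(rows, axis=0),
         (center + R * u)[None, :]])          # apex of the head cap
    apex_idx = verts.shape[0] - 1

    def ring_idx(j):
        return 1 + j * nth + np.arange(nth)

    faces = []
    # distal pole fan
    r0 = ring_idx(0)
    for k in range(nth):
        faces.append([0, r0[(k + 1) % nth], r0[k]])
    # quad strips
    for j in range(n_rows - 1):
        a = ring_idx(j)
        b = ring_idx(j + 1)
        for k in range(nth):
            k2 = (k + 1) % nth
            faces.append([a[k], a[k2], b[k]])
            faces.append([a[k2], b[k2], b[k]])
    # apex fan
    top = ring_idx(n_rows - 1)
    for k in range(nth):
        faces.append([top[k], top[(k + 1) % nth], apex_idx])

    mesh = TriangleMesh(verts, np.asarray(faces, dtype=np.int64))

    # landmarks (grid positions are latent-independent)
    articular = np.concatenate([ring_idx(j) for j in
                                range(cap_row_start, n_rows)] + [[apex_idx]])
    k_med = 0
    k_lat = int(round(_THETA_LATERAL / (2 * np.pi / nth))) % nth
    j_epi = int(np.argmin(np.abs(grid.tube_t - _T_EPI)))
    j_del = int(np.argmin(np.abs(grid.tube_t - _T_DELTOID)))
    head_sup = articular[int(np.argmax(verts[articular, 2]))]
    landmarks = LandmarkIndex(
        articular_surface=articular,
        epicondyle_medial_caudal=np.array([ring_idx(j_epi)[k_med]]),
        epicondyle_lateral_caudal=np.array([ring_idx(j_epi)[k_lat]]),
        trochlea_inferior=np.array([0]),
        head_superior=np.array([head_sup]),
        deltoid_tuberosity=np.array([ring_idx(j_del)[k_lat]]),
    )
    return mesh, landmarks


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def build_template(resolution: float = 1.5,
                   latent: HumerusLatent | None = None) -> HumerusTemplate:
    """Canonical humerus-like mesh plus landmark sets at a target mean edge
    length of ``resolution`` mm (honoured within about ±35%)."""
    latent = latent or HumerusLatent()
    grid = _make_grid(resolution, latent)
    mesh, landmarks = _evaluate(grid, latent)
    return HumerusTemplate(mesh=mesh, landmarks=landmarks, grid=grid,
                           latent=latent)


def instantiate(template: HumerusTemplate, latent: HumerusLatent) -> TriangleMesh:
    """Realise a latent vector on the template grid (identical topology)."""
    mesh, _ = _evaluate(template.grid, latent)
    return mesh


def expected_measurements(template: HumerusTemplate,
                          latent: HumerusLatent) -> dict:
    """Ground-truth values of the three geometric parameters as built.

    The shaft circumference is the exact perimeter of the generated
    cross-section polygon at the deltoid-tuberosity level.
    """
    grid = template.grid
    nth = grid.n_theta
    theta = np.arange(nth) * (2 * np.pi / nth)
    j_del = int(np.argmin(np.abs(grid.tube_t - _T_DELTOID)))
    t_del = grid.tube_t[j_del]
    r = _radius_field(np.full(nth, t_del), theta, latent)
    ring = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    perim = float(np.linalg.norm(np.roll(ring, -1, axis=0) - ring,
                                 axis=1).sum())
    return {
        "max_length": latent.length,
        "head_radius": latent.head_radius,
        "shaft_circumference": perim,
    }


def _draw_latents(rng: np.random.Generator, means: HumerusLatent,
                  sds: dict, n: int) -> list[HumerusLatent]:
    """Independent truncated-normal draws per field; joint invariants are
    enforced by redrawing the offending rows."""
    mu = means.as_array()
    sd = np.array([sds.get(f, 0.0) for f in LATENT_FIELDS])
    out = []
    for _ in range(n):
        for _attempt in range(200):
            x = mu + sd * rng.standard_normal(len(LATENT_FIELDS))
            try:
                out.append(HumerusLatent.from_array(x))
                break
            except ParameterError:
                continue
        else:
            raise ParameterError("latent sampling cannot satisfy invariants; "
                                 "check means/sds")
    return out


def sample_population(spec: PopulationSpec,
                      template: HumerusTemplate | None = None):
    """Draw a corresponded population; returns (shape set, latent table).

    The latent table (list of :class:`HumerusLatent`, one per shape, in
    shape order) is the ground truth for parameter-recovery tests.
    """
    template = template or build_template(spec.template_resolution,
                                          spec.latent_means)
    rng = np.random.default_rng(spec.seed)
    latents = _draw_latents(rng, spec.latent_means, spec.latent_sds, spec.n)
    shapes = np.stack([instantiate(template, la).vertices for la in latents])
    shape_set = CorrespondedShapeSet(
        faces=template.mesh.faces, shapes=shapes,
        labels=[f"synthetic_{i:03d}" for i in range(spec.n)])
    return shape_set, latents


SAGITTAL_PLANE = Plane(point=np.zeros(3), normal=np.array([1.0, 0.0, 0.0]))


def generate_bilateral_pair(template: HumerusTemplate, latent: HumerusLatent,
                            asymmetry_sds: dict | None = None,
                            seed: int = 0):
    """A left humerus and its (mirrored) right counterpart.

    The right side is instantiated from the latent plus independent normal
    asymmetry noise per field, then reflected across the sagittal plane;
    zero asymmetry gives a perfectly mirrored pair.
    """
    asymmetry_sds = asymmetry_sds or {}
    unknown = set(asymmetry_sds) - set(LATENT_FIELDS)
    if unknown:
        raise ParameterError(f"unknown latent fields {sorted(unknown)}")
    left = instantiate(template, latent)
    rng = np.random.default_rng(seed)
    sd = np.array([asymmetry_sds.get(f, 0.0) for f in LATENT_FIELDS])
    for _attempt in range(200):
        x = latent.as_array() + sd * rng.standard_normal(len(LATENT_FIELDS))
        try:
            right_latent = HumerusLatent.from_array(x)
            break
        except ParameterError:
            continue
    else:
        raise ParameterError("asymmetry sampling cannot satisfy invariants")
    right = mirror_mesh(instantiate(template, right_latent), SAGITTAL_PLANE)
    return left, right, right_latent
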