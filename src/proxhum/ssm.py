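"""Point-distribution shape model: PCA over corresponded vertex sets.

The model is S = mu + sum_i w_i m_i: a mean shape vector mu (length 3N),
orthonormal modes of variation m_i and per-mode standard deviations.  Mode
weights are stored in standard-deviation units — the conventional "-3 SD to
+3 SD" visualisation scale — so the millimetre-scale weighting factor of a
shape is ``values[i] * mode_sds[i]``.

Because 3N far exceeds the number of training shapes M, the
eigendecomposition runs on the M x M Gram matrix; a direct-covariance
route exists only in tests as an independent oracle.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .errors import DataError, ParameterError
from .mesh_core import TriangleMesh
from .registration import CorrespondedShapeSet

_EIG_REL_THRESHOLD = 1e-12
# absolute floor: per-mode variance below (1e-7 mm)^2 is numerical noise
# for mm-scale coordinates (e.g. a training set of identical shapes)
_EIG_ABS_FLOOR = 1e-14


@dataclasses.dataclass(frozen=True)
class ShapeModel:
    """Linear point-distribution model over a fixed triangulation."""

    mean_vector: np.ndarray   # (3N,)
    modes: np.ndarray         # (3N, K), orthonormal columns
    mode_sds: np.ndarray      # (K,), non-increasing, mm
    faces: np.ndarray         # (F, 3)
    n_training: int

    def __post_init__(self) -> None:
        mu = np.asarray(self.mean_vector, dtype=np.float64).ravel()
        P = np.asarray(self.modes, dtype=np.float64)
        s = np.asarray(self.mode_sds, dtype=np.float64).ravel()
        if P.ndim != 2 or P.shape[0] != mu.size:
            raise ParameterError("modes must be (3N, K)")
        if s.size != P.shape[1]:
            raise ParameterError("one sd per mode required")
        if s.size:
            if np.any(np.diff(s) > 1e-12) or np.any(s < 0):
                raise ParameterError("mode_sds must be non-increasing and >= 0")
            if np.abs(P.T @ P - np.eye(s.size)).max() > 1e-8:
                raise ParameterError("mode columns are not orthonormal")
        if s.size > min(mu.size, self.n_training - 1):
            raise ParameterError("more modes than the data can support")
        object.__setattr__(self, "mean_vector", mu)
        object.__setattr__(self, "modes", P)
        object.__setattr__(self, "mode_sds", s)
        object.__setattr__(self, "faces",
                           np.asarray(self.faces, dtype=np.int64))

    @property
    def n_modes(self) -> int:
        return self.mode_sds.size

    @property
    def n_vertices(self) -> int:
        return self.mean_vector.size // 3

    def mean_mesh(self) -> TriangleMesh:
        return TriangleMesh(self.mean_vector.reshape(-1, 3), self.faces)


@dataclasses.dataclass(frozen=True)
class ModeWeights:
    """Mode weights in sd units (weight 1 = one mode standard deviation)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(v)):
            raise ParameterError("weights must be finite")
        object.__setattr__(self, "values", v)


@dataclasses.dataclass(frozen=True)
class CompactnessCurve:
    """Cumulative fraction of training variance per mode count."""

    cumulative_variance_fraction: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.cumulative_variance_fraction, dtype=np.float64)
        if c.size and (np.any(np.diff(c) < -1e-12)
                       or abs(c[-1] - 1.0) > 1e-9):
            raise ParameterError("compactness curve must be non-decreasing "
                                 "and end at 1")
        object.__setattr__(self, "cumulative_variance_fraction", c)


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def pca_from_vectors(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of row vectors via the Gram-matrix trick.

    Returns (mean, modes with orthonormal columns, per-mode sds) using the
    sample-covariance divisor M - 1 and a deterministic sign convention:
    each mode's largest-magnitude entry is positive.
    """
    X = np.asarray(X, dtype=np.float64)
    m = X.shape[0]
    if m < 2:
        raise DataError("PCA needs at least 2 training vectors")
    mu = X.mean(axis=0)
    D = X - mu
    # thin SVD of the M-column matrix: the numerically stable form of the
    # M x M Gram-matrix route (same eigenpairs, exactly orthonormal modes)
    U, s, _ = np.linalg.svd(D.T, full_matrices=False)
    evals = s ** 2 / (m - 1)
    keep = evals > max(_EIG_REL_THRESHOLD * (evals[0] if evals.size else 0.0),
                       _EIG_ABS_FLOOR)
    evals, modes = evals[keep], U[:, keep]
    sds = np.sqrt(evals)
    # deterministic signs
    if modes.size:
        flip = np.sign(modes[np.abs(modes).argmax(axis=0),
                             np.arange(modes.shape[1])])
        modes = modes * flip
    return mu, modes, sds


def build_ssm(shapes: CorrespondedShapeSet) -> ShapeModel:
    """Fit the point-distribution model to an aligned, corresponded set."""
    if shapes.n_shapes < 2:
        raise DataError("need at least 2 shapes to build a model")
    X = shapes.shapes.reshape(shapes.n_shapes, -1)
    mu, modes, sds = pca_from_vectors(X)
    return ShapeModel(mean_vector=mu, modes=modes, mode_sds=sds,
                      faces=shapes.faces, n_training=shapes.n_shapes)


# ---------------------------------------------------------------------------
# Synthesis / projection / compactness
# ---------------------------------------------------------------------------

def synthesize_vector(model: ShapeModel, weights: ModeWeights) -> np.ndarray:
    w = weights.values
    if w.size != model.n_modes:
        raise ParameterError(
            f"expected {model.n_modes} weights, got {w.size}")
    return model.mean_vector + model.modes @ (w * model.mode_sds)


def synthesize(model: ShapeModel, weights: ModeWeights) -> TriangleMesh:
    """Realise S = mu + sum_i (values_i * sd_i) m_i as a mesh."""
    return TriangleMesh(synthesize_vector(model, weights).reshape(-1, 3),
                        model.faces)


def project(model: ShapeModel, shape) -> ModeWeights:
    """Mode weights (sd units) of a corresponded shape in the model frame.

    Modes with zero sd get weight 0: they carry no training variance and a
    finite weight there would be meaningless.
    """
    x = np.asarray(shape, dtype=np.float64).ravel()
    if x.size != model.mean_vector.size:
        raise ParameterError("shape does not match model dimension")
    coeff = model.modes.T @ (x - model.mean_vector)
    safe = np.where(model.mode_sds > 0, model.mode_sds, 1.0)
    values = np.where(model.mode_sds > 0, coeff / safe, 0.0)
    return ModeWeights(values=values)


def compactness(model: ShapeModel) -> CompactnessCurve:
    """Cumulative eigenvalue fractions — how few modes carry the variance."""
    var = model.mode_sds ** 2
    if var.size == 0:
        return CompactnessCurve(np.empty(0))
    c = np.cumsum(var) / var.sum()
    c[-1] = 1.0
    return CompactnessCurve(c)


def modes_for_variance(model: ShapeModel, fraction: float) -> int:
    """Smallest mode count whose cumulative variance reaches ``fraction``."""
    if not 0.0 < fraction <= 1.0:
        raise ParameterError("fraction must be in (0, 1]")
    curve = compactness(model).cumulative_variance_fraction
    if curve.size == 0:
        return 0
    return int(np.searchsorted(curve, fraction - 1e-12) + 1)


# ---------------------------------------------------------------------------
# Serialization: .npz archive with a JSON header entry
# ---------------------------------------------------------------------------

_MODEL_FORMAT = "proxhum-ssm-1"


def save_model(model: ShapeModel, path, extra_header: dict | None = None) -> None:
    """Single-archive serialization: JSON header + named arrays (npz)."""
    header = {"format": _MODEL_FORMAT, "n_training": model.n_training}
    header.update(extra_header or {})
    np.savez(path,
             header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
             mean_vector=model.mean_vector, modes=model.modes,
             mode_sds=model.mode_sds, faces=model.faces)


def load_model(path) -> tuple[ShapeModel, dict]:
    with np.load(path) as z:
        header = json.loads(bytes(z["header"]).decode())
        if header.get("format") != _MODEL_FORMAT:
            raise DataError(f"unrecognised model format {header.get('format')!r}")
        model = ShapeModel(mean_vector=z["mean_vector"], modes=z["modes"],
                           mode_sds=z["mode_sds"], faces=z["faces"],
                           n_training=int(header["n_training"]))
    return model, header
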