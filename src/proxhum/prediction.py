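"""Measurement-conditioned shape prediction.

The core pathway of the package: scalar geometric measurements are appended
to each training shape vector, PCA is re-run on the augmented vectors, and
a full bone shape is predicted by fixing the measurement entries at target
values.  With mode weights expressed in sd units the model is a standard
Gaussian, so "fix the measurements" has a canonical answer: the conditional
expectation of the shape block given the measurement block.  It is computed
as the minimum-Mahalanobis-norm solve

    min ||w||^2   subject to   A w = b,

where A collects the measurement rows of the (sd-scaled) modes and b the
standardized targets; the least-norm solution coincides with the joint-
Gaussian conditional mean whenever the measurement sub-covariance is
nonsingular, and tests verify this against the closed-form Schur-complement
oracle.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .errors import DataError, MeasurementError, ParameterError
from .measurements import MeasurementSet
from .mesh_core import TriangleMesh
from .registration import CorrespondedShapeSet
from .ssm import ModeWeights, pca_from_vectors

#: Ridge on the constrained solve; guards near-collinear measurements
#: (length and radius correlate in realistic populations).
_CONDITION_RIDGE = 1e-8

#: Fraction of total augmented variance carried by the measurement block
#: under the default "balanced" scale policy.
_BALANCE_FRACTION = 0.01


@dataclasses.dataclass(frozen=True)
class AugmentedShapeModel:
    """PCA model over [3N shape coordinates ; scaled measurements].

    The measurement entries occupy the trailing ``len(measurement_names)``
    positions of ``mean_vector`` and ``modes``.  Measurements are
    standardized to unit training sd and multiplied by ``measurement_scale``
    before PCA, so the scale controls how much augmented variance the
    measurement block carries without changing what conditioning enforces.
    """

    mean_vector: np.ndarray
    modes: np.ndarray
    mode_sds: np.ndarray
    faces: np.ndarray
    n_training: int
    measurement_names: tuple[str, ...]
    measurement_scale: np.ndarray
    measurement_means: np.ndarray
    measurement_sds: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean_vector",
                           np.asarray(self.mean_vector, dtype=np.float64))
        object.__setattr__(self, "modes",
                           np.asarray(self.modes, dtype=np.float64))
        object.__setattr__(self, "mode_sds",
                           np.asarray(self.mode_sds, dtype=np.float64))
        object.__setattr__(self, "faces",
                           np.asarray(self.faces, dtype=np.int64))
        for name in ("measurement_scale", "measurement_means", "measurement_sds"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=np.float64))
        if np.any(self.measurement_scale <= 0):
            raise ParameterError("measurement scales must be positive")
        q = len(self.measurement_names)
        if not (self.measurement_scale.size == self.measurement_means.size
                == self.measurement_sds.size == q):
            raise ParameterError("measurement metadata sizes disagree")

    @property
    def n_measurements(self) -> int:
        return len(self.measurement_names)

    @property
    def n_modes(self) -> int:
        return self.mode_sds.size

    @property
    def n_vertices(self) -> int:
        return (self.mean_vector.size - self.n_measurements) // 3

    def shape_block(self, vector: np.ndarray) -> np.ndarray:
        return vector[: 3 * self.n_vertices]

    def measurement_block(self, vector: np.ndarray) -> np.ndarray:
        return vector[3 * self.n_vertices:]


@dataclasses.dataclass(frozen=True)
class PredictionResult:
    predicted_mesh: TriangleMesh
    achieved_measurements: MeasurementSet
    weights_used: ModeWeights
    conditioning_residual: float    # mm, ||achieved - target||
    out_of_range: bool              # any target > 5 training sds from mean

    def __post_init__(self) -> None:
        if self.conditioning_residual < 0:
            raise ParameterError("conditioning_residual must be >= 0")


# ---------------------------------------------------------------------------
# Model building
# ---------------------------------------------------------------------------

def build_augmented_ssm(shapes: CorrespondedShapeSet,
                        measurements: list[MeasurementSet],
                        which=("max_length", "head_radius"),
                        scale_policy="balanced") -> AugmentedShapeModel:
    """PCA over shape vectors augmented with standardized measurements.

    ``scale_policy`` is either the string ``"balanced"`` (measurement block
    sized to carry about 1% of total augmented variance — enough to steer
    conditioning, too little to distort the shape modes) or a positive
    float applied to every standardized measurement.
    """
    which = tuple(which)
    if shapes.n_shapes < 3:
        raise DataError("augmented model needs at least 3 shapes")
    if len(measurements) != shapes.n_shapes:
        raise DataError("one MeasurementSet per training shape required")
    try:
        M = np.stack([ms.values_for(which) for ms in measurements])
    except MeasurementError as exc:
        raise DataError(f"training measurement missing: {exc}") from exc

    X = shapes.shapes.reshape(shapes.n_shapes, -1)
    m_mean = M.mean(axis=0)
    m_sd = M.std(axis=0, ddof=1)
    if np.any(m_sd <= 0):
        # a constant measurement adds no information: its standardized
        # column is zero and the shape modes are unchanged
        degenerate = [w for w, s in zip(which, m_sd) if s <= 0]
        warnings.warn(f"zero-variance measurements {degenerate} cannot "
                      "steer conditioning", stacklevel=2)
        m_sd = np.where(m_sd > 0, m_sd, 1.0)
    if scale_policy == "balanced":
        shape_var = X.var(axis=0, ddof=1).sum()
        scale_val = np.sqrt(_BALANCE_FRACTION * shape_var / len(which))
        scale = np.full(len(which), scale_val)
    else:
        scale_val = float(scale_policy)
        if scale_val <= 0:
            raise ParameterError("scale_policy must be 'balanced' or > 0")
        scale = np.full(len(which), scale_val)

    Z = np.hstack([X, scale * (M - m_mean) / m_sd])
    mu, modes, sds = pca_from_vectors(Z)
    return AugmentedShapeModel(
        mean_vector=mu, modes=modes, mode_sds=sds, faces=shapes.faces,
        n_training=shapes.n_shapes, measurement_names=which,
        measurement_scale=scale, measurement_means=m_mean,
        measurement_sds=m_sd)


# ---------------------------------------------------------------------------
# Conditioning
# ---------------------------------------------------------------------------

def predict_from_measurements(model: AugmentedShapeModel,
                              targets: MeasurementSet) -> PredictionResult:
    """Predict the full shape whose measurement block matches ``targets``.

    Solves the least-norm problem in sd-unit mode space (see module
    docstring); targets far outside the training range (> 5 training sds)
    set a warning flag rather than erroring — fracture cases legitimately
    sit at population extremes.
    """
    names = model.measurement_names
    if set(targets.present()) != set(names):
        raise MeasurementError(
            f"targets must cover exactly {names}, got {targets.present()}")
    t = targets.values_for(names)
    z_t = (t - model.measurement_means) / model.measurement_sds
    out_of_range = bool(np.any(np.abs(z_t) > 5.0))

    b = model.measurement_scale * z_t - model.measurement_block(model.mean_vector)
    A = model.modes[3 * model.n_vertices:, :] * model.mode_sds[None, :]
    AAt = A @ A.T
    w = A.T @ np.linalg.solve(AAt + _CONDITION_RIDGE * np.eye(len(b)), b)

    vec = model.mean_vector + model.modes @ (model.mode_sds * w)
    mesh = TriangleMesh(model.shape_block(vec).reshape(-1, 3), model.faces)
    achieved_scaled = model.measurement_block(vec)
    achieved_mm = (model.measurement_means
                   + model.measurement_sds * achieved_scaled / model.measurement_scale)
    residual = float(np.linalg.norm(achieved_mm - t))
    achieved = MeasurementSet(**dict(zip(names, achieved_mm)))
    return PredictionResult(predicted_mesh=mesh, achieved_measurements=achieved,
                            weights_used=ModeWeights(w),
                            conditioning_residual=residual,
                            out_of_range=out_of_range)


def conditional_mean_oracle(train_vectors: np.ndarray, q: int,
                            targets: np.ndarray) -> np.ndarray:
    """Closed-form joint-Gaussian conditional mean (Schur complement).

    Independent of the mode-space solve: partitions the raw training
    covariance into shape/measurement blocks and returns
    ``mu_s + C_sm C_mm^{-1} (t - mu_m)``.  Used as the test oracle for
    :func:`predict_from_measurements` on small instances.
    """
    Z = np.asarray(train_vectors, dtype=np.float64)
    mu = Z.mean(axis=0)
    D = Z - mu
    C = D.T @ D / (Z.shape[0] - 1)
    C_sm = C[:-q, -q:]
    C_mm = C[-q:, -q:]
    return mu[:-q] + C_sm @ np.linalg.solve(C_mm, targets - mu[-q:])


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_AUG_FORMAT = "proxhum-augmented-ssm-1"


def save_augmented_model(model: AugmentedShapeModel, path) -> None:
    import json

    header = {"format": _AUG_FORMAT, "n_training": model.n_training,
              "measurement_names": list(model.measurement_names)}
    np.savez(path,
             header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
             mean_vector=model.mean_vector, modes=model.modes,
             mode_sds=model.mode_sds, faces=model.faces,
             measurement_scale=model.measurement_scale,
             measurement_means=model.measurement_means,
             measurement_sds=model.measurement_sds)


def load_augmented_model(path) -> AugmentedShapeModel:
    import json

    with np.load(path) as z:
        header = json.loads(bytes(z["header"]).decode())
        if header.get("format") != _AUG_FORMAT:
            raise DataError(
                f"unrecognised model format {header.get('format')!r}")
        return AugmentedShapeModel(
            mean_vector=z["mean_vector"], modes=z["modes"],
            mode_sds=z["mode_sds"], faces=z["faces"],
            n_training=int(header["n_training"]),
            measurement_names=tuple(header["measurement_names"]),
            measurement_scale=z["measurement_scale"],
            measurement_means=z["measurement_means"],
            measurement_sds=z["measurement_sds"])


# ---------------------------------------------------------------------------
# Combination experiment (the seven measurement subsets)
# ---------------------------------------------------------------------------

ALL_COMBINATIONS: tuple[tuple[str, ...], ...] = (
    ("max_length",),
    ("head_radius",),
    ("shaft_circumference",),
    ("max_length", "head_radius"),
    ("max_length", "shaft_circumference"),
    ("head_radius", "shaft_circumference"),
    ("max_length", "head_radius", "shaft_circumference"),
)


def evaluate_combinations(train_shapes: CorrespondedShapeSet,
                          train_measurements: list[MeasurementSet],
                          test_meshes: list[TriangleMesh],
                          test_measurements: list[MeasurementSet],
                          combinations=ALL_COMBINATIONS,
                          cut_distance: float | None = None,
                          proximal_hints: list[np.ndarray] | None = None,
                          segment_template: TriangleMesh | None = None):
    """Prediction accuracy for each measurement combination.

    For every combination an augmented model is built, each test humerus is
    predicted from its own measured values, and the proximal-segment
    deviation is evaluated; the table reports mean/sd of the %-area with
    deviation > 2 mm and of the maximum deviation.  Returns a pandas
    DataFrame with one row per combination.
    """
    import pandas as pd

    from .config import PROXIMAL_CUT_DISTANCE_MM
    from .evaluation import compare_prediction

    if cut_distance is None:
        cut_distance = PROXIMAL_CUT_DISTANCE_MM
    rows = []
    for combo in combinations:
        model = build_augmented_ssm(train_shapes, train_measurements, combo)
        pct_over, max_dev = [], []
        for i, (mesh, ms) in enumerate(zip(test_meshes, test_measurements)):
            targets = MeasurementSet(**{k: getattr(ms, k) for k in combo})
            pred = predict_from_measurements(model, targets)
            hint = None if proximal_hints is None else proximal_hints[i]
            dev = compare_prediction(mesh, pred.predicted_mesh,
                                     cut_distance=cut_distance,
                                     proximal_hint=hint,
                                     segment_template=segment_template)
            pct_over.append(100.0 * dev.bin_fractions[2])
            max_dev.append(dev.max_abs)
        rows.append({
            "combination": "+".join(combo),
            "pct_area_over_2mm_mean": float(np.mean(pct_over)),
            "pct_area_over_2mm_sd": float(np.std(pct_over, ddof=1)) if len(pct_over) > 1 else 0.0,
            "max_deviation_mm_mean": float(np.mean(max_dev)),
            "max_deviation_mm_sd": float(np.std(max_dev, ddof=1)) if len(max_dev) > 1 else 0.0,
        })
    return pd.DataFrame(rows)
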