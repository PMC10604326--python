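"""Proximal-segment extraction, deviation maps, and the two-arm experiment.

The clinical question is how well a reconstruction template matches the
true proximal humerus — the upper 60 mm of the bone, cut perpendicular to
the diaphysis axis.  Two templates are compared: the measurement-
conditioned shape-model prediction, and the mirrored contralateral bone
(the clinical gold standard).  "Part comparison" is a per-point signed
point-to-surface distance map over the candidate segment, area-binned at
1 mm and at the clinically relevant 2 mm threshold.

Sign convention: positive deviation means the candidate surface lies
outside the original — an overestimation (the reconstruction is wider than
the bone).
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .config import (
    DEVIATION_THRESHOLDS_MM,
    PROXIMAL_CUT_DISTANCE_MM,
    SEGMENT_TEMPLATE_POINTS,
)
from .errors import EmptyMeshError, ParameterError
from .measurements import MeasurementSet, build_hcs, measure_all
from .mesh_core import (
    Plane,
    SurfaceQuery,
    TriangleMesh,
    cut_mesh_by_plane,
    fit_cylinder_axis,
    mirror_mesh,
)
from .registration import icp_rigid, warp_template
from .synthetic import (
    SAGITTAL_PLANE,
    HumerusTemplate,
    PopulationSpec,
    build_template,
    generate_bilateral_pair,
    sample_population,
)

_METHODS = ("ssm_prediction", "contralateral")
_BIN_LABELS = ("0-1mm", "1-2mm", ">2mm")


# ---------------------------------------------------------------------------
# Deviation maps
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class DeviationMap:
    """Signed distances from segment A's vertices to segment B's surface.

    ``bin_fractions`` are fractions of A's surface area with absolute
    deviation in [0,1), [1,2) and [2,inf) mm; they sum to 1.
    """

    signed_distances: np.ndarray
    bin_fractions: np.ndarray
    max_abs: float
    mean_signed: float
    segment_a: TriangleMesh | None = None  # geometry of A, for export

    def __post_init__(self) -> None:
        object.__setattr__(self, "signed_distances",
                           np.asarray(self.signed_distances, dtype=np.float64))
        bf = np.asarray(self.bin_fractions, dtype=np.float64)
        if abs(bf.sum() - 1.0) > 1e-9:
            raise ParameterError("bin fractions must sum to 1")
        if self.max_abs < 0:
            raise ParameterError("max_abs must be >= 0")
        object.__setattr__(self, "bin_fractions", bf)


def deviation_map(segA: TriangleMesh, segB: TriangleMesh,
                  thresholds=DEVIATION_THRESHOLDS_MM) -> DeviationMap:
    """Per-vertex signed point-to-surface distance of A against B.

    Vertices are weighted by one third of their incident triangle areas so
    the bin fractions are surface-area fractions, not vertex counts.
    """
    if segA.n_faces == 0 or segB.n_faces == 0:
        raise EmptyMeshError("deviation map needs two non-empty segments")
    signed = SurfaceQuery(segB).signed_distance(segA.vertices)
    w = segA.vertex_areas()
    w = w / w.sum()
    a = np.abs(signed)
    t1, t2 = thresholds
    fractions = np.array([w[a < t1].sum(),
                          w[(a >= t1) & (a < t2)].sum(),
                          w[a >= t2].sum()])
    fractions = fractions / fractions.sum()
    return DeviationMap(signed_distances=signed, bin_fractions=fractions,
                        max_abs=float(a.max()),
                        mean_signed=float(w @ signed),
                        segment_a=segA)


# ---------------------------------------------------------------------------
# Segment extraction and correspondence
# ---------------------------------------------------------------------------

def _diaphysis_axis(mesh: TriangleMesh, proximal_hint: np.ndarray | None):
    """Diaphysis cylinder axis, oriented to point proximally.

    Mid-shaft vertices (central 40% of the long-axis extent) feed the
    cylinder fit.  Without an explicit hint, the proximal end is taken to
    be the end with the larger mean radial spread over its outer 60 mm —
    the head and tuberosities are wide over a long span, while the distal
    widening is confined to the very end.
    """
    v = mesh.vertices
    c = v.mean(axis=0)
    _, _, vt = np.linalg.svd(v - c, full_matrices=False)
    long_dir = vt[0]
    s = (v - c) @ long_dir
    lo, hi = s.min(), s.max()
    band = (s > lo + 0.30 * (hi - lo)) & (s < lo + 0.70 * (hi - lo))
    axis = fit_cylinder_axis(v[band])
    d = axis.direction
    s_ax = (v - axis.point) @ d
    if proximal_hint is not None:
        if (np.asarray(proximal_hint) - axis.point) @ d < np.median(s_ax):
            d = -d
    else:
        radial = np.linalg.norm((v - axis.point)
                                - np.outer(s_ax, d), axis=1)
        span = 60.0
        hi_mask = s_ax > s_ax.max() - span
        lo_mask = s_ax < s_ax.min() + span
        if radial[lo_mask].mean() > radial[hi_mask].mean():
            d = -d
    return axis.point, d


def extract_proximal_segment(mesh: TriangleMesh,
                             cut_distance: float = PROXIMAL_CUT_DISTANCE_MM,
                             proximal_hint: np.ndarray | None = None) -> TriangleMesh:
    """The upper part of the bone: everything within ``cut_distance`` mm of
    the most proximal point, measured along the diaphysis axis; uncapped."""
    point, d = _diaphysis_axis(mesh, proximal_hint)
    s = (mesh.vertices - point) @ d
    extent = float(s.max() - s.min())
    # 0.5 mm slack: "full length" measured along any near-axial direction
    # may differ from the axis extent by a sub-resolution amount
    if cut_distance > extent + 0.5:
        raise ParameterError(
            f"cut distance {cut_distance} mm exceeds bone extent "
            f"{extent:.1f} mm")
    if cut_distance >= extent:
        return mesh
    origin = point + (s.max() - cut_distance) * d
    return cut_mesh_by_plane(mesh, Plane(point=origin, normal=d), keep="positive")


def correspond_segments(segA: TriangleMesh, segB: TriangleMesh,
                        n_points: int = SEGMENT_TEMPLATE_POINTS,
                        template: TriangleMesh | None = None):
    """Warp one common template onto both segments -> equal point counts.

    When no template is supplied the first segment serves as the common
    template (its own vertex count then stands in for ``n_points``); the
    experiment pipeline passes the model-mean segment so both arms share
    one segment topology of approximately ``n_points`` vertices.
    Returns the two corresponded vertex arrays (template topology).
    """
    if template is None:
        template = segA
    warpedA = template if template is segA else warp_template(template, segA)
    warpedB = warp_template(template, segB)
    return warpedA.vertices, warpedB.vertices, template.faces


# ---------------------------------------------------------------------------
# The two comparison arms
# ---------------------------------------------------------------------------

def compare_prediction(original: TriangleMesh, predicted: TriangleMesh,
                       cut_distance: float = PROXIMAL_CUT_DISTANCE_MM,
                       proximal_hint: np.ndarray | None = None,
                       segment_template: TriangleMesh | None = None) -> DeviationMap:
    """Deviation of a reconstruction template against the original bone.

    Rigidly aligns the candidate to the original (no scaling), extracts
    both proximal segments, establishes equal point counts by warping, and
    maps the candidate's deviation from the original segment; positive
    mean deviation = overestimation (candidate wider than the bone).
    ``proximal_hint`` (a point near the humeral head, in the original's
    frame) disambiguates which end is proximal; after alignment it is valid
    for both meshes.
    """
    tf = icp_rigid(predicted, original)
    candidate = tf.apply_mesh(predicted)
    seg_orig = extract_proximal_segment(original, cut_distance, proximal_hint)
    seg_cand = extract_proximal_segment(candidate, cut_distance, proximal_hint)
    vA, vB, faces = correspond_segments(seg_cand, seg_orig,
                                        template=segment_template)
    return deviation_map(TriangleMesh(vA, faces), TriangleMesh(vB, faces))


def compare_contralateral(left: TriangleMesh, right: TriangleMesh,
                          cut_distance: float = PROXIMAL_CUT_DISTANCE_MM,
                          proximal_hint: np.ndarray | None = None,
                          mirror_plane: Plane = SAGITTAL_PLANE,
                          segment_template: TriangleMesh | None = None) -> DeviationMap:
    """Contralateral registration arm: mirror the right bone, then run the
    identical pipeline with the mirrored bone as the candidate."""
    mirrored = mirror_mesh(right, mirror_plane)
    return compare_prediction(left, mirrored, cut_distance=cut_distance,
                              proximal_hint=proximal_hint,
                              segment_template=segment_template)


# ---------------------------------------------------------------------------
# End-to-end validation experiment
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ComparisonReport:
    """Per-specimen bin fractions and per-method aggregates (percent)."""

    per_specimen: "object"     # pandas DataFrame
    aggregate: "object"        # pandas DataFrame: bins x methods, mean/sd
    config: dict

    def to_json(self) -> str:
        return json.dumps({
            "config": self.config,
            "per_specimen": self.per_specimen.to_dict(orient="records"),
            "aggregate": self.aggregate.reset_index().to_dict(orient="records"),
        }, indent=2)


def run_validation_experiment(training_spec: PopulationSpec,
                              n_validation_pairs: int = 8,
                              asymmetry_sds: dict | None = None,
                              which_measurements=("max_length", "head_radius"),
                              seed: int = 0,
                              cut_distance: float = PROXIMAL_CUT_DISTANCE_MM,
                              template: HumerusTemplate | None = None) -> ComparisonReport:
    """Shape-model prediction versus contralateral registration.

    Builds a synthetic training population, fits the measurement-augmented
    shape model, generates held-out bilateral pairs, and runs both
    comparison arms on each pair's proximal segment.  The aggregate table
    has one row per deviation bin and mean/sd columns per method; the three
    bin means sum to 100% for each method.
    """
    import pandas as pd

    from .prediction import build_augmented_ssm, predict_from_measurements
    from .registration import align_set

    template = template or build_template(training_spec.template_resolution,
                                          training_spec.latent_means)
    landmarks = template.landmarks
    train_set, _ = sample_population(training_spec, template)
    aligned = align_set(train_set)
    train_meas = []
    for i in range(aligned.n_shapes):
        mesh = aligned.mesh(i)
        hcs = build_hcs(mesh, landmarks)
        train_meas.append(measure_all(mesh, hcs, landmarks, which_measurements))
    model = build_augmented_ssm(aligned, train_meas, which_measurements)

    # segment template: the model-mean proximal segment (deterministic and
    # available to both arms)
    mean_mesh = TriangleMesh(model.shape_block(model.mean_vector).reshape(-1, 3),
                             model.faces)
    mean_head = mean_mesh.vertices[landmarks.articular_surface].mean(axis=0)
    segment_template = extract_proximal_segment(mean_mesh, cut_distance,
                                                proximal_hint=mean_head)

    rng = np.random.default_rng(seed)
    pair_latents = _validation_latents(training_spec, rng, n_validation_pairs)

    records = []
    for i, latent in enumerate(pair_latents):
        pair_seed = int(rng.integers(0, 2 ** 31 - 1))
        left, right, _ = generate_bilateral_pair(template, latent,
                                                 asymmetry_sds, seed=pair_seed)
        head_hint = left.vertices[landmarks.articular_surface].mean(axis=0)

        hcs = build_hcs(left, landmarks)
        meas = measure_all(left, hcs, landmarks, which_measurements)
        pred = predict_from_measurements(model, meas)

        dev_ssm = compare_prediction(left, pred.predicted_mesh,
                                     cut_distance=cut_distance,
                                     proximal_hint=head_hint,
                                     segment_template=segment_template)
        dev_con = compare_contralateral(left, right, cut_distance=cut_distance,
                                        proximal_hint=head_hint,
                                        segment_template=segment_template)
        for method, dev in (("ssm_prediction", dev_ssm),
                            ("contralateral", dev_con)):
            records.append({
                "specimen": i, "method": method,
                **{f"pct_{lbl}": 100.0 * frac
                   for lbl, frac in zip(_BIN_LABELS, dev.bin_fractions)},
                "max_abs_mm": dev.max_abs,
                "mean_signed_mm": dev.mean_signed,
            })

    per_specimen = pd.DataFrame(records)
    agg_rows = []
    for lbl in _BIN_LABELS:
        row = {"bin": lbl}
        for method in _METHODS:
            vals = per_specimen.loc[per_specimen["method"] == method,
                                    f"pct_{lbl}"]
            row[f"{method}_mean"] = float(vals.mean())
            row[f"{method}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        agg_rows.append(row)
    aggregate = pd.DataFrame(agg_rows).set_index("bin")
    config = {
        "n_training": training_spec.n,
        "n_validation_pairs": n_validation_pairs,
        "which_measurements": list(which_measurements),
        "asymmetry_sds": asymmetry_sds or {},
        "seed": seed,
        "cut_distance_mm": cut_distance,
        "template_resolution_mm": training_spec.template_resolution,
    }
    return ComparisonReport(per_specimen=per_specimen, aggregate=aggregate,
                            config=config)


def _validation_latents(spec: PopulationSpec, rng, n_pairs):
    from .synthetic import _draw_latents
    return _draw_latents(rng, spec.latent_means, spec.latent_sds, n_pairs)
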