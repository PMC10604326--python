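# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `proxhum`. All lengths are millimetres (STL carries no
units; CT exports conventionally use mm) and all coordinate frames are
right-handed.

## Shape model

Shapes are point-distribution models: M training bones corresponded to a
common triangulation with N vertices, each flattened to a 3N-vector. After
generalized Procrustes alignment over rotations and translations only (no
scaling — size is anatomy, not pose), the model is the PCA decomposition

    S = μ + Σᵢ wᵢ mᵢ ,

with sample covariance divisor M−1. Because 3N ≫ M, the eigenpairs are
obtained from the M-dimensional problem (thin SVD of the centred data
matrix, the numerically stable equivalent of the M×M Gram-matrix route);
a brute-force covariance eigendecomposition serves as an independent
oracle in the tests. Mode weights are stored in per-mode standard
deviation units — the familiar "−3 SD … +3 SD" visualisation scale — and
the millimetre weighting factor is recoverable as `values[i] * mode_sds[i]`.
Eigenvector signs are arbitrary; the convention here makes each mode's
largest-magnitude entry positive so repeated fits are bit-identical.
Eigenvalues below 1e−12 of the largest (or below an absolute floor of
(1e−7 mm)², relevant only for degenerate training sets) are treated as
zero. Whether the covariance divisor is M or M−1 does not affect any
variance *fraction* (compactness); M−1 is used throughout.

## Correspondence and alignment

Rigid ICP matches every source vertex to its exact closest point on the
target surface (point-to-triangle, lowest face index on ties for
determinism) and solves the Kabsch/SVD problem with scale fixed at 1 and
reflection explicitly excluded, so mirrored inputs are never absorbed into
the pose. Manual pre-alignment of interactive workflows is replaced by a
centroid + principal-axes initialisation; the four sign disambiguations of
a right-handed principal frame are scored by matched distance and the best
is refined.

Dense correspondence is established by warping a reference mesh onto each
target with Laplacian-regularised non-rigid ICP. At each stiffness level α
the displacement field D solves the sparse linear least-squares problem

    min Σᵢ [ ((vᵢ + dᵢ − cᵢ)·nᵢ)² + β‖vᵢ + dᵢ − cᵢ‖² ] + α Σ_{(i,j)∈E} ‖dᵢ − dⱼ‖²

where cᵢ is the current closest point on the target, nᵢ its triangle
normal and E the template edge graph. The *point-to-plane* data term is
essential: on featureless regions (a near-cylindrical shaft, the spherical
head) a point-to-point spring resists the tangential sliding needed to
distribute stretch, whereas the point-to-plane term leaves it free and the
Laplacian distributes it harmonically — which is exactly the uniform
parameterisation the synthetic ground truth uses. The small point-to-point
weight β = 0.05 keeps the system nonsingular. The stiffness schedule
{1000, 100, 10, 1} with 10 inner iterations per level is a conventional
coarse-to-fine choice; on synthetic ground truth at 1.5 mm resolution the
warp lands within 1 mm (99th percentile) of the true corresponding
vertices and within 0.2 mm of the target surface.

A fundamental identifiability caveat: tangential correspondence on an
exactly rotationally symmetric patch (the articular sphere) is
unobservable from geometry alone. The validation of correspondence
quality therefore varies size-like latent factors; rotational factors
(neck-shaft angle) are validated through the downstream surface-distance
metrics, which are insensitive to tangential sliding.

## Closest-point queries

`trimesh` supplies file I/O and plane slicing, but its proximity queries
require an R-tree index; `proxhum` instead uses its own vectorised query:
candidate triangles from a k-d tree over triangle centroids (k = 16
candidates), exact point-triangle projection on the candidates, ties
broken toward the lowest face index. On the smooth, uniformly meshed
surfaces this pipeline handles, the nearest triangle's centroid is always
among the candidates.

## Anatomical measurements

The humeral coordinate system follows the ISB-style construction: origin
at the centre of a sphere fitted to the articular surface (linear Kåsa
solve plus one Gauss–Newton refinement pass), Y axis from the epicondylar
midpoint through the head centre (proximal positive), X normal to the
plane of origin and the two caudal epicondylar points (lateral positive),
Z completing the triad (Z is made exactly orthogonal; X is recomputed).

* **Maximum length** — distance between the two extreme supporting planes
  normal to Y. Extremes are taken over vertices, not interpolated surface
  points; at the working resolutions the difference is far below the
  0.5 mm recovery tolerance. The plane-based definition is used
  throughout; for all anatomies generated here the most distal vertex is
  the inferior trochlear point, so the plane-based and landmark-based
  definitions coincide.
* **Head radius** — radius of the fitted articular sphere.
* **Shaft circumference** — perimeter of the cross-section cut normal to
  Y at the level of the deltoid-tuberosity landmark (the most protruding
  mid-diaphysis point). Among the section's closed contours, the one
  enclosing the Y axis is measured; the landmark-level definition makes
  the measurement deterministic and observer-free.

Landmarks are defined once on the template and propagated through
correspondence. Note that STL files do not preserve vertex order (facets
are stored independently), so landmark indices remain valid only for
order-preserving formats (PLY/OBJ) or for meshes kept in memory; the CLI's
simulated cohorts rely on permutation-insensitive uses (the articular
*set*, ring-level landmarks) which survive the STL round trip at the
working resolutions.

Intra-observer reliability uses the two-way mixed-effects,
absolute-agreement, single-measure intraclass correlation computed from
the two-way ANOVA mean squares; the form had to be chosen (conventions
differ) and ICC(A,1) is the standard reliability choice for repeated
measurements by one observer. It is cross-checked against
`pingouin.intraclass_corr` in the tests.

## Measurement-conditioned prediction

Each training vector is augmented with its measurements, standardized to
unit training SD and multiplied by a balance factor sized so the
measurement block carries ~1% of the total augmented variance — enough to
steer conditioning, too little to distort the shape modes. The factor is
immaterial to the result (tests cover three orders of magnitude) because
conditioning constrains the block exactly: prediction solves

    min ‖w‖²  subject to  A w = b

in SD-unit mode space (A = measurement rows of the SD-scaled modes, b the
standardized targets), with a ridge of 1e−8 guarding near-collinear
measurements (length and radius correlate in realistic populations). The
least-norm solution in whitened coordinates *is* the joint-Gaussian
conditional mean whenever the measurement sub-covariance is nonsingular;
the tests verify this against a closed-form Schur-complement oracle. A
hard constraint was chosen over a soft (regularized-regression) variant
because it is the canonical "set a target value for the measurements"
semantics and is exactly testable. Targets more than 5 training SDs from
the mean set a warning flag rather than raising — fracture cases may
legitimately sit at population extremes.

## Deviation evaluation

The proximal segment is everything within 60 mm (configurable) of the
most proximal point measured along the diaphysis axis: a cylinder fit to
the mid-shaft vertex band (central 40% of the long-axis extent),
initialised from the covariance eigenvectors (both the largest- and the
smallest-spread directions are tried) and refined by nonlinear least
squares on the radial-distance variance. The axis is computed per bone in
its own frame, which is rigid-invariant. Orientation (which end is
proximal) comes from an optional hint point (the head centroid, available
whenever landmarks are) or, without one, from the larger mean radial
spread over the outer 60 mm of each end — the head and tuberosities are
wide over a long span, the distal widening only at the very end. Cut
surfaces are left uncapped: the comparison is between surfaces, and a cap
would pollute the area statistics.

"Part comparison" is the signed point-to-surface distance from the
candidate segment's vertices to the original segment, positive when the
candidate lies outside (an overestimation — the reconstruction is wider
than the bone). Fractions per deviation bin ([0,1), [1,2), [2,∞) mm; the
2 mm threshold is the clinically relevant displacement) are weighted by
barycentric vertex areas, i.e. they are *surface-area* fractions, not
vertex counts; bins use absolute deviation, while signed summaries
(mean, per-vertex map) are reported alongside. Before mapping, both
segments are warped from a common segment template (the model-mean
segment in the experiment pipeline, the candidate segment when none is
given) so both arms of the comparison are evaluated on equal point
counts; the default template size constant is 1952 points, honoured
approximately since the parametric generator controls vertex count only
through resolution.

The contralateral arm mirrors the opposite-side bone across the sagittal
plane x = 0 and then runs the identical pipeline. The specific mirror
plane is immaterial — any reflection differs only by a rigid motion,
which the subsequent ICP removes.

## Synthetic anatomy

The generator emulates a healthy adult cohort with seven latent factors:
maximum length (default 310 mm), head radius (24 mm), shaft radius
(10 mm), neck-shaft angle (135°), medial head offset (6 mm), deltoid
prominence (2 mm) and epicondylar width (60 mm) — generator conventions
at realistic anatomical magnitudes, with population SDs (18, 1.8, 1.0,
5°, 1.0, 0.5, 3.5) chosen to emulate healthy variation. Latents are drawn
from independent truncated normals (re-drawn when a joint invariant such
as head_radius < length/4 fails, a rare event at the default spreads).

A bone is a generalized cylinder around the long axis — radius bumps for
the epicondyles, trochlea and deltoid tuberosity, an elliptic distal
closure — joined by a blended neck band to a spherical articular cap
tilted by the neck-shaft angle and offset medially. All instances are
evaluated on one fixed (row, angle) grid, so correspondence is exact by
construction, landmark vertex sets are known, and the latent-to-shape map
is near-linear: a noiseless k-factor population has ≥99.9% of its
variance in k modes, which is what makes rank and conditional-mean
oracles exact. Bilateral pairs add independent per-field asymmetry noise
to the right side before mirroring.

What the generator does **not** emulate: real cortical/trabecular
anatomy, segmentation noise, remeshing artefacts, pathology, and —
importantly — the residual nonlinearity and unmodelled detail of real
bone populations. Passing tests therefore demonstrate the correctness of
the algorithms under known ground truth, not clinical accuracy on CT
data; cohort-level percentages from the synthetic experiment are
conditions-dependent and not comparable to any specific clinical cohort.

## Problem sizes and defaults

The working resolution for study-scale runs is 3.5 mm mean edge length
(~2400 vertices per bone; the generator supports 0.5–5 mm and targets the
requested resolution within ±35%). The packaged experiment uses 100
training bones and 8 held-out bilateral pairs, with asymmetry SDs
(shaft_radius 0.4 mm, head_offset 0.4 mm, deltoid_prominence 0.3 mm)
representing modest left–right differences. The repeat-measurement ICC
simulation perturbs true lengths with 0.5 mm observer noise per session —
a realistic manual re-measurement precision on a ~300 mm bone. Unit tests
run at 4.0–4.5 mm resolution; the warp-correspondence oracle runs once at
1.5 mm, the pipeline's reference resolution.

## Known limitations

* Correspondence is geometry-driven; no landmark-guided or
  intensity-based registration, and no automatic landmark detection.
* The conditional model is linear-Gaussian; no posterior uncertainty or
  sampling around the conditional mean.
* Prediction from partial surfaces (e.g. an intact distal segment) is out
  of scope, as are neck-shaft-angle prediction, mesh repair beyond vertex
  merging, and DICOM/segmentation input.
* `extract_proximal_segment` without a hint relies on a radial-spread
  heuristic that assumes humerus-like proportions.
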