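"""Named pipeline constants and the run configuration container.

The defaults encode the conventions of the clinical workflow the package
implements: deviations between a reconstructed and an original proximal
humerus are binned at 1 mm and 2 mm (2 mm being the clinically relevant
displacement threshold), the proximal segment is the upper 60 mm of the
bone measured along the diaphysis axis, segment meshes are resampled to
roughly 1952 points before comparison, and surface meshes target a mean
triangular edge length of 1.5 mm.  All lengths are millimetres: STL carries
no units and CT-derived exports conventionally use mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .errors import ParameterError

#: Deviation bin edges in mm; bins are [0,1), [1,2), [2, inf).
DEVIATION_THRESHOLDS_MM: tuple[float, float] = (1.0, 2.0)

#: Clinically relevant deviation threshold (mm).
CLINICAL_THRESHOLD_MM: float = 2.0

#: Distance from the most proximal point to the diaphysis cut (mm).
PROXIMAL_CUT_DISTANCE_MM: float = 60.0

#: Target vertex count of the common proximal-segment template.
SEGMENT_TEMPLATE_POINTS: int = 1952

#: Target mean triangular edge length of generated meshes (mm).
DEFAULT_EDGE_LENGTH_MM: float = 1.5

#: Coarse-to-fine stiffness schedule for non-rigid template warping.
DEFAULT_STIFFNESS_SCHEDULE: tuple[float, ...] = (1000.0, 100.0, 10.0, 1.0)

#: Vertex merge tolerance on mesh read (mm).
VERTEX_MERGE_TOL_MM: float = 1e-6

FORMAT_VERSION: str = "1"


@dataclass
class RunConfig:
    """Reproducibility envelope for a pipeline run.

    Collects the knobs shared across subcommands; CLI flags override fields
    loaded from a YAML config.
    """

    seed: int = 0
    thresholds_mm: tuple[float, float] = DEVIATION_THRESHOLDS_MM
    cut_distance_mm: float = PROXIMAL_CUT_DISTANCE_MM
    segment_points: int = SEGMENT_TEMPLATE_POINTS
    resolution_mm: float = DEFAULT_EDGE_LENGTH_MM
    stiffness_schedule: tuple[float, ...] = DEFAULT_STIFFNESS_SCHEDULE
    measurements: tuple[str, ...] = ("max_length", "head_radius")
    format_version: str = FORMAT_VERSION
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.thresholds_mm)
        if len(t) != 2 or t[0] <= 0 or t[1] <= t[0]:
            raise ParameterError(
                f"thresholds must be strictly increasing and positive, got {t}"
            )
        self.thresholds_mm = t
        if not (isinstance(self.seed, int) and self.seed >= 0):
            raise ParameterError(f"seed must be a non-negative integer, got {self.seed!r}")
        self.stiffness_schedule = tuple(float(s) for s in self.stiffness_schedule)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds_mm"] = list(self.thresholds_mm)
        d["stiffness_schedule"] = list(self.stiffness_schedule)
        d["measurements"] = list(self.measurements)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in d.items() if k in known}
        return cls(**kwargs)
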