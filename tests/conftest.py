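"""Shared fixtures: coarse synthetic anatomy reused across test modules.

Generation is deterministic, so session-scoped fixtures are safe; tests
must not mutate them (TriangleMesh arrays are read-only).
"""

import numpy as np
import pytest
import trimesh

import proxhum as px

#: Coarse grid used in most tests: fast, yet fine enough for the geometric
#: tolerances exercised here.
COARSE_RES = 4.0


@pytest.fixture(scope="session")
def template():
    return px.build_template(COARSE_RES)


@pytest.fixture(scope="session")
def humerus(template):
    return template.mesh


@pytest.fixture(scope="session")
def population(template):
    spec = px.PopulationSpec(n=25, seed=42, template_resolution=COARSE_RES)
    shapes, latents = px.sample_population(spec, template)
    return shapes, latents


@pytest.fixture(scope="session")
def aligned_population(population):
    shapes, latents = population
    return px.align_set(shapes), latents


@pytest.fixture(scope="session")
def measured_population(aligned_population, template):
    aligned, latents = aligned_population
    sets = []
    for i in range(aligned.n_shapes):
        mesh = aligned.mesh(i)
        hcs = px.build_hcs(mesh, template.landmarks)
        sets.append(px.measure_all(mesh, hcs, template.landmarks))
    return aligned, latents, sets


@pytest.fixture(scope="session")
def unit_tetrahedron():
    v = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                  [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return px.TriangleMesh(v, f)


def icosphere(radius: float, subdivisions: int = 4) -> px.TriangleMesh:
    return px.TriangleMesh.from_trimesh(
        trimesh.creation.icosphere(subdivisions, radius))


def random_rigid(rng, max_angle_deg=180.0, max_translation=50.0) -> px.RigidTransform:
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0, max_angle_deg))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    t = rng.uniform(-max_translation, max_translation, 3)
    return px.RigidTransform(R, t)
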