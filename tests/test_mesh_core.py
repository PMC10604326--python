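"""Mesh data model, I/O, geometric primitives and least-squares fits."""

import numpy as np
import pytest

import proxhum as px
from proxhum.errors import (
    DegeneracyError,
    EmptyMeshError,
    MeshFormatError,
    ParameterError,
)

from conftest import icosphere, random_rigid

# ASCII STL: two facets sharing an edge, coordinates duplicated per facet
TWO_FACET_STL = """solid pair
facet normal 0 0 1
 outer loop
  vertex 0 0 0
  vertex 1 0 0
  vertex 0 1 0
 endloop
endfacet
facet normal 0 0 1
 outer loop
  vertex 1 0 0
  vertex 1 1 0
  vertex 0 1 0
 endloop
endfacet
endsolid pair
"""


class TestIO:
    def test_tetrahedron_stl_round_trip(self, unit_tetrahedron, tmp_path):
        path = tmp_path / "tet.stl"
        px.write_mesh(unit_tetrahedron, path)
        back = px.read_mesh(path)
        assert back.n_vertices == 4
        assert back.n_faces == 4
        # vertex sets equal (order may change on STL read)
        a = np.sort(unit_tetrahedron.vertices.round(9).view("f8,f8,f8"), axis=0)
        b = np.sort(back.vertices.round(9).view("f8,f8,f8"), axis=0)
        assert np.array_equal(a, b)

    def test_duplicate_facet_vertices_merged(self, tmp_path):
        path = tmp_path / "pair.stl"
        path.write_text(TWO_FACET_STL)
        mesh = px.read_mesh(path)
        assert mesh.n_vertices == 4  # 6 stored, 2 duplicates merged
        assert mesh.n_faces == 2

    def test_humerus_round_trip_preserves_vertices(self, humerus, tmp_path):
        path = tmp_path / "h.stl"
        px.write_mesh(humerus, path)
        back = px.read_mesh(path)
        assert back.n_faces == humerus.n_faces
        a = np.sort(humerus.vertices.ravel())
        b = np.sort(back.vertices.ravel())
        assert np.abs(a - b).max() < 1e-5

    @pytest.mark.parametrize("fmt", ["ply", "obj"])
    def test_cross_format_round_trips_agree(self, fmt, tmp_path):
        mesh = icosphere(24.0, 2)
        p1 = tmp_path / f"m.{fmt}"
        p2 = tmp_path / "m.stl"
        px.write_mesh(mesh, p1)
        px.write_mesh(mesh, p2)
        b1 = px.read_mesh(p1)
        b2 = px.read_mesh(p2)
        assert b1.n_faces == b2.n_faces
        a = np.sort(b1.vertices.ravel())
        b = np.sort(b2.vertices.ravel())
        assert np.abs(a - b).max() < 1e-5

    def test_missing_file_errors_with_path(self, tmp_path):
        with pytest.raises(IOError, match="nope.stl"):
            px.read_mesh(tmp_path / "nope.stl")

    def test_garbage_content_is_format_error(self, tmp_path):
        path = tmp_path / "bad.ply"
        path.write_text("this is not a mesh")
        with pytest.raises(MeshFormatError):
            px.read_mesh(path)

    def test_unsupported_format_rejected(self, tmp_path):
        with pytest.raises(ParameterError):
            px.read_mesh(tmp_path / "x.vtk")


class TestTriangleMeshInvariants:
    def test_rejects_nonfinite(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [np.nan, 0, 1.0]])
        f = np.array([[0, 1, 2], [0, 1, 3]])
        with pytest.raises(ParameterError):
            px.TriangleMesh(v, f)

    def test_rejects_bad_indices(self, unit_tetrahedron):
        with pytest.raises(ParameterError):
            px.TriangleMesh(unit_tetrahedron.vertices, [[0, 1, 9]])

    def test_drops_degenerate_faces(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        f = np.array([[0, 1, 2], [1, 1, 2], [0, 1, 3]])  # middle is zero-area
        mesh = px.TriangleMesh(v, f)
        assert mesh.n_faces == 2

    def test_all_degenerate_is_empty_error(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0.0]])
        with pytest.raises(EmptyMeshError):
            px.TriangleMesh(v, [[0, 1, 2], [1, 2, 3]])


class TestEdgeLengthAndMirror:
    def test_tetrahedron_unit_edges(self):
        # regular tetrahedron, all edges length 1
        v = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                     dtype=float) / np.sqrt(8)
        f = [[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]]
        assert np.isclose(px.mean_edge_length(px.TriangleMesh(v, f)), 1.0)

    def test_icosahedron_edge_two(self):
        import trimesh
        ico = trimesh.creation.icosahedron()
        edge = np.linalg.norm(ico.vertices[ico.edges_unique[0][0]]
                              - ico.vertices[ico.edges_unique[0][1]])
        mesh = px.TriangleMesh(np.asarray(ico.vertices) * (2.0 / edge),
                               np.asarray(ico.faces))
        assert np.isclose(px.mean_edge_length(mesh), 2.0)

    def test_generated_humerus_edge_near_target(self, humerus):
        # generator calibration: within +-35% of the requested resolution
        assert 0.65 * 4.0 <= px.mean_edge_length(humerus) <= 1.35 * 4.0

    def test_mirror_is_involution(self, humerus):
        plane = px.Plane(point=[3.0, -2.0, 7.0], normal=[1.0, 2.0, -1.0])
        twice = px.mirror_mesh(px.mirror_mesh(humerus, plane), plane)
        assert np.abs(twice.vertices - humerus.vertices).max() < 1e-9

    def test_mirror_point_across_x0(self, unit_tetrahedron):
        plane = px.Plane(point=[0, 0, 0], normal=[1, 0, 0])
        mirrored = px.mirror_mesh(unit_tetrahedron, plane)
        assert np.allclose(mirrored.vertices[1], [-1, 0, 0])

    def test_mirror_preserves_area(self, humerus):
        plane = px.Plane(point=[1.0, 2.0, 3.0], normal=[0.2, -1.0, 0.5])
        mirrored = px.mirror_mesh(humerus, plane)
        assert np.isclose(mirrored.area(), humerus.area(), rtol=1e-6)


class TestPlaneCut:
    @pytest.fixture()
    def cube(self):
        import trimesh
        return px.TriangleMesh.from_trimesh(
            trimesh.creation.box(extents=[10.0, 10.0, 10.0]))

    def test_half_cube_area_without_cap(self, cube):
        plane = px.Plane(point=[0, 0, 0], normal=[0, 0, 1])
        kept = px.cut_mesh_by_plane(cube, plane, keep="positive")
        # one full face (100) + four half faces (4 x 50), no cap
        assert np.isclose(kept.area(), 300.0, rtol=1e-9)

    def test_cut_conserves_area(self, cube, humerus):
        for mesh in (cube, humerus):
            plane = px.Plane(point=mesh.vertices.mean(axis=0),
                             normal=[0.3, 0.5, 0.8])
            kept = px.cut_mesh_by_plane(mesh, plane, "positive")
            rest = px.cut_mesh_by_plane(mesh, plane, "negative")
            assert np.isclose(kept.area() + rest.area(), mesh.area(),
                              rtol=1e-6)

    def test_plane_below_keeps_everything(self, cube):
        plane = px.Plane(point=[0, 0, -100.0], normal=[0, 0, 1])
        kept = px.cut_mesh_by_plane(cube, plane, "positive")
        assert kept.n_faces == cube.n_faces
        assert np.isclose(kept.area(), cube.area())

    def test_plane_above_is_empty_error(self, cube):
        plane = px.Plane(point=[0, 0, 100.0], normal=[0, 0, 1])
        with pytest.raises(EmptyMeshError):
            px.cut_mesh_by_plane(cube, plane, "positive")

    def test_half_sphere_area(self):
        sphere = icosphere(24.0, 4)
        plane = px.Plane(point=[0, 0, 0], normal=[0, 0, 1])
        kept = px.cut_mesh_by_plane(sphere, plane, "positive")
        # analytic hemisphere area; polyhedral deficit stays within 2%
        assert np.isclose(kept.area(), 2 * np.pi * 24.0 ** 2, rtol=0.02)


class TestFitSphere:
    @staticmethod
    def sphere_points(center, radius, n=200, seed=0, noise=0.0):
        rng = np.random.default_rng(seed)
        d = rng.standard_normal((n, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        pts = center + radius * d
        if noise:
            pts = pts + rng.normal(0, noise, pts.shape)
        return pts

    def test_exact_points(self):
        fit = px.fit_sphere(self.sphere_points([1, 2, 3], 24.0))
        assert np.allclose(fit.center, [1, 2, 3], atol=1e-9)
        assert np.isclose(fit.radius, 24.0, atol=1e-9)
        assert fit.rms_residual < 1e-9

    def test_noisy_radius_unbiased(self):
        # Monte-Carlo: radius estimate stays within 0.05 mm at noise sd 0.1
        radii = [px.fit_sphere(self.sphere_points([1, 2, 3], 24.0, seed=s,
                                                  noise=0.1)).radius
                 for s in range(50)]
        assert abs(np.mean(radii) - 24.0) < 0.05

    def test_hemispherical_cap(self):
        # 60-degree aperture cap, mimicking a partial articular surface
        rng = np.random.default_rng(3)
        phi = np.arccos(rng.uniform(np.cos(np.deg2rad(60)), 1.0, 300))
        theta = rng.uniform(0, 2 * np.pi, 300)
        pts = 24.0 * np.column_stack([np.sin(phi) * np.cos(theta),
                                      np.sin(phi) * np.sin(theta),
                                      np.cos(phi)])
        fit = px.fit_sphere(pts + np.array([5.0, -1.0, 2.0]))
        assert np.isclose(fit.radius, 24.0, atol=1e-6)

    def test_coplanar_degeneracy(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(-1, 1, 50),
                               rng.uniform(-1, 1, 50), np.zeros(50)])
        with pytest.raises(DegeneracyError):
            px.fit_sphere(pts)

    def test_rigid_equivariance(self):
        pts = self.sphere_points([0, 0, 0], 10.0, seed=1, noise=0.05)
        tf = random_rigid(np.random.default_rng(7))
        fit0 = px.fit_sphere(pts)
        fit1 = px.fit_sphere(tf.apply(pts))
        assert np.allclose(tf.apply(fit0.center), fit1.center, atol=1e-6)
        assert np.isclose(fit0.radius, fit1.radius, atol=1e-8)


class TestFitCylinderAxis:
    @staticmethod
    def cylinder_points(radius=10.0, height=100.0, n=400, seed=0, taper=0.0):
        rng = np.random.default_rng(seed)
        z = rng.uniform(-height / 2, height / 2, n)
        theta = rng.uniform(0, 2 * np.pi, n)
        r = radius + taper * (z / height)
        return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])

    def test_exact_axis(self):
        fit = px.fit_cylinder_axis(self.cylinder_points())
        assert abs(abs(fit.direction[2]) - 1.0) < 1e-6

    def test_tapered_frustum_within_half_degree(self):
        pts = self.cylinder_points(radius=9.0, taper=-2.0, seed=2)
        fit = px.fit_cylinder_axis(pts)
        angle = np.arccos(min(abs(fit.direction[2]), 1.0))
        assert np.rad2deg(angle) < 0.5

    def test_rotation_equivariance(self):
        pts = self.cylinder_points(seed=5)
        tf = random_rigid(np.random.default_rng(11))
        fit0 = px.fit_cylinder_axis(pts)
        fit1 = px.fit_cylinder_axis(tf.apply(pts))
        d0 = tf.rotation @ fit0.direction
        angle = np.arccos(min(abs(d0 @ fit1.direction), 1.0))
        assert angle < 1e-6

    def test_spherical_cloud_degenerate(self):
        pts = TestFitSphere.sphere_points([0, 0, 0], 10.0, n=300)
        with pytest.raises(DegeneracyError):
            px.fit_cylinder_axis(pts)


class TestSurfaceQuery:
    def test_signed_distance_sign_convention(self):
        sphere = icosphere(10.0, 3)
        q = px.SurfaceQuery(sphere)
        outside = q.signed_distance(np.array([[0, 0, 15.0]]))
        inside = q.signed_distance(np.array([[0, 0, 5.0]]))
        assert outside[0] > 0
        assert inside[0] < 0

    def test_exact_on_surface(self, humerus):
        q = px.SurfaceQuery(humerus)
        _, d, _ = q.query(humerus.vertices[::17])
        assert d.max() < 1e-9
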