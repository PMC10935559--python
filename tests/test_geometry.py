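"""Synthetic bench geometry: groove height field, icosphere, mesh quality."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from pftwin.errors import DomainError, MeshError, ToleranceError
from pftwin.geometry import (GrooveParams, HeightFieldReference, MeshQuality,
                             SphereReference, TriMesh, load_mesh,
                             make_icosphere, make_trochlear_surface,
                             mesh_quality, save_mesh)

COARSE = MeshQuality(1e-4, 1.0)


class TestGrooveParams:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            GrooveParams(groove_depth=-1e-3)
        with pytest.raises(ValueError):
            GrooveParams(arc_extent=4.0)
        with pytest.raises(ValueError):
            GrooveParams(lateral_ridge_gain=0.9, medial_ridge_gain=1.0)

    def test_ridges_are_stationary_with_prescribed_heights(self):
        g = GrooveParams(lateral_ridge_gain=1.2, medial_ridge_gain=1.0)
        w, d = g.groove_halfwidth, g.groove_depth
        assert g.medial_ridge_height == pytest.approx(1.0 * d)
        assert g.lateral_ridge_height == pytest.approx(1.2 * d)
        h = 1e-7
        for y in (w, -w):
            dz = (g.height(0.0, y + h) - g.height(0.0, y - h)) / (2 * h)
            assert abs(dz) < 1e-6

    def test_lateral_ridge_higher_when_gain_larger(self):
        g = GrooveParams(lateral_ridge_gain=1.3, medial_ridge_gain=1.0)
        assert g.lateral_ridge_height > g.medial_ridge_height

    def test_polynomial_coefficients_reproduce_height(self, rng):
        g = GrooveParams()
        coefs = g.polynomial_coefficients()
        x = rng.uniform(-g.x_halfwidth, g.x_halfwidth, 50)
        y = rng.uniform(-g.y_halfwidth, g.y_halfwidth, 50)
        z = sum(c * x ** i * y ** j for (i, j), c in coefs.items())
        assert np.allclose(z, g.height(x, y), atol=1e-15)


class TestTrochlearSurface:
    def test_vertices_lie_exactly_on_the_analytic_form(self, groove):
        mesh = make_trochlear_surface(groove, COARSE)
        res = np.abs(mesh.vertices[:, 2]
                     - groove.height(mesh.vertices[:, 0], mesh.vertices[:, 1]))
        assert res.max() < 1e-12

    def test_measured_quality_meets_requested_target(self, groove,
                                                     groove_reference):
        mesh = make_trochlear_surface(groove, COARSE)
        q = mesh_quality(mesh, groove_reference)
        assert q.within(COARSE)

    def test_refinement_is_second_order_in_edge_length(self, groove,
                                                       groove_reference):
        from pftwin.geometry import _grid_mesh
        q1 = mesh_quality(_grid_mesh(groove, 24, 80), groove_reference)
        q2 = mesh_quality(_grid_mesh(groove, 48, 160), groove_reference)
        ratio = q1.max_chordal_deviation / q2.max_chordal_deviation
        assert 3.0 < ratio < 5.0

    def test_symmetric_gains_give_mirror_symmetric_mesh(self):
        g = GrooveParams(lateral_ridge_gain=1.0, medial_ridge_gain=1.0)
        mesh = make_trochlear_surface(g, COARSE)
        mirrored = mesh.vertices * np.array([1.0, -1.0, 1.0])
        d, _ = cKDTree(mesh.vertices).query(mirrored)
        assert d.max() < 1e-12

    def test_unreachable_tolerance_raises(self, groove):
        with pytest.raises(ToleranceError):
            make_trochlear_surface(groove, MeshQuality(1e-12, 1e-4))

    def test_density_weight_concentrates_lateral_grid_lines(self, groove):
        w = groove.groove_halfwidth
        mesh = make_trochlear_surface(
            groove, COARSE, density=lambda y: 1.0 + 9.0 * (y < -0.5 * w))
        ys = np.unique(np.round(mesh.vertices[:, 1], 12))
        lateral = np.sum(ys < -0.5 * w)
        medial = np.sum(ys > 0.5 * w)
        assert lateral > 2 * medial


class TestIcosphere:
    @pytest.mark.parametrize("sub,faces,verts", [(0, 20, 12), (3, 1280, None)])
    def test_face_and_vertex_counts(self, sub, faces, verts):
        m = make_icosphere(0.015, sub)
        assert m.n_faces == faces
        if verts is not None:
            assert m.n_vertices == verts

    def test_vertices_on_sphere(self):
        m = make_icosphere(0.015, 2)
        r = np.linalg.norm(m.vertices, axis=1)
        assert np.abs(r - 0.015).max() < 1e-12

    def test_chordal_deviation_strictly_decreases_with_subdivision(self):
        ref = SphereReference(0.1)
        devs = [mesh_quality(make_icosphere(0.1, s), ref).max_chordal_deviation
                for s in range(4)]
        assert all(a > b for a, b in zip(devs, devs[1:]))

    def test_guards(self):
        with pytest.raises(ValueError):
            make_icosphere(-1.0, 0)
        with pytest.raises(MeshError):
            make_icosphere(0.01, 99)


class TestMeshQuality:
    def test_plane_mesh_vs_plane_reference_is_zero(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        f = np.array([[0, 1, 2], [0, 2, 3]])
        q = mesh_quality(TriMesh(v, f), lambda x, y: 0.0 * x)
        assert q.max_chordal_deviation == pytest.approx(0.0, abs=1e-15)
        assert q.max_normal_deviation == pytest.approx(0.0, abs=1e-10)

    def test_matches_bruteforce_per_face_maximum(self):
        mesh = make_icosphere(0.05, 2)
        q = mesh_quality(mesh, SphereReference(0.05))
        worst = 0.0
        for tri in mesh.triangles:            # exhaustive loop oracle
            c = tri.mean(axis=0)
            worst = max(worst, abs(np.linalg.norm(c) - 0.05))
        assert q.max_chordal_deviation == pytest.approx(worst, rel=1e-12)

    def test_centroid_outside_domain_raises(self, groove):
        ref = HeightFieldReference.from_groove(groove)
        v = np.array([[10.0, 0, 0], [11.0, 0, 0], [10.0, 1.0, 0]])
        with pytest.raises(DomainError):
            mesh_quality(TriMesh(v, np.array([[0, 1, 2]])), ref)


class TestMeshIO:
    def test_obj_roundtrip_preserves_vertex_order(self, tmp_path):
        mesh = make_icosphere(0.02, 1)
        save_mesh(mesh, tmp_path / "m.obj")
        back = load_mesh(tmp_path / "m.obj")
        assert np.allclose(back.vertices, mesh.vertices)
        assert np.array_equal(back.faces, mesh.faces)

    def test_stl_roundtrip_preserves_geometry(self, tmp_path):
        mesh = make_icosphere(0.02, 1)
        save_mesh(mesh, tmp_path / "m.stl")
        back = load_mesh(tmp_path / "m.stl")
        assert back.n_faces == mesh.n_faces
        # same triangle soup up to vertex re-welding
        a = np.sort(np.round(mesh.triangles.reshape(-1, 3), 9), axis=0)
        b = np.sort(np.round(back.triangles.reshape(-1, 3), 9), axis=0)
        assert np.allclose(a, b, atol=1e-6)

    def test_degenerate_face_rejected(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        m = TriMesh(v, np.array([[0, 1, 2]]))
        with pytest.raises(MeshError):
            m.validate()
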