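"""Collision backends: AABB tree, triangle intersection, contact patches."""

import numpy as np
import pytest

from pftwin.collision import (AnalyticContactBackend, MeshContactBackend,
                              SpherePrimitive, build_aabb_tree, closest_point,
                              query_candidates, sphere_surface_contact)
from pftwin.collision.aabb import query_pairs
from pftwin.collision.contact import ContactPatch, EpisodeTracker
from pftwin.collision.tritri import (point_triangle_closest, tri_tri_segment,
                                     tri_tri_segments_batch)
from pftwin.errors import MeshError
from pftwin.geometry import TriMesh, make_icosphere
from pftwin.surface_fit import PolynomialSurface, fit_polynomial, n_coefficients

I3 = np.eye(3)
ZERO = np.zeros(3)


def plane_mesh(n=50, lim=0.12, z=0.0):
    xs = np.linspace(-lim, lim, n)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    V = np.stack([X.ravel(), Y.ravel(), np.full(n * n, z)], axis=1)
    i, j = np.meshgrid(np.arange(n - 1), np.arange(n - 1), indexing="ij")
    v00 = (i * n + j).ravel()
    v10 = ((i + 1) * n + j).ravel()
    v01 = (i * n + j + 1).ravel()
    v11 = ((i + 1) * n + j + 1).ravel()
    F = np.concatenate([np.stack([v00, v10, v11], 1),
                        np.stack([v00, v11, v01], 1)])
    return TriMesh(V, F)


class TestAABBTree:
    def test_single_triangle_tree(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        t = build_aabb_tree(TriMesh(v, np.array([[0, 1, 2]])))
        assert t.n_nodes == 1
        assert np.allclose(t.lower[0], [0, 0, 0])
        assert np.allclose(t.upper[0], [1, 1, 0])

    def test_empty_mesh_rejected(self):
        m = TriMesh(np.zeros((3, 3)), np.zeros((0, 3), int))
        with pytest.raises(MeshError):
            build_aabb_tree(m)

    def test_depth_near_log2_under_median_split(self):
        mesh = make_icosphere(0.05, 2)          # 320 faces
        tree = build_aabb_tree(mesh)
        assert tree.depth() <= int(np.ceil(np.log2(mesh.n_faces))) + 2

    def test_leaf_boxes_contain_their_triangles(self):
        mesh = make_icosphere(0.05, 1)
        tree = build_aabb_tree(mesh)
        leaf = tree.leaf_for_triangle()
        for k, tri in enumerate(mesh.triangles):
            node = leaf[k]
            assert np.all(tri >= tree.lower[node] - 1e-15)
            assert np.all(tri <= tree.upper[node] + 1e-15)

    def test_whole_mesh_probe_returns_all_triangles(self):
        mesh = make_icosphere(0.05, 2)
        tree = build_aabb_tree(mesh)
        got = query_candidates(tree, [-1, -1, -1], [1, 1, 1])
        assert np.array_equal(got, np.arange(mesh.n_faces))

    def test_disjoint_probe_returns_nothing(self):
        tree = build_aabb_tree(make_icosphere(0.05, 2))
        assert len(query_candidates(tree, [1, 1, 1], [2, 2, 2])) == 0

    def test_random_probes_match_bruteforce(self, rng):
        mesh = make_icosphere(0.05, 2)
        tree = build_aabb_tree(mesh)
        for _ in range(100):
            c = rng.uniform(-0.06, 0.06, 3)
            half = rng.uniform(0.002, 0.04, 3)
            lo, hi = c - half, c + half
            got = set(query_candidates(tree, lo, hi).tolist())
            brute = set(np.nonzero(np.all((tree.tri_upper >= lo)
                                          & (tree.tri_lower <= hi),
                                          axis=1))[0].tolist())
            assert got == brute

    def test_dual_tree_pairs_match_bruteforce(self, rng):
        a = make_icosphere(0.03, 1)
        b = make_icosphere(0.03, 1)
        ta, tb = build_aabb_tree(a), build_aabb_tree(b)
        R = np.eye(3)
        t = np.array([0.045, 0.01, 0.0])
        pairs = {tuple(map(int, p)) for p in query_pairs(ta, tb, R, t)}
        blo = tb.tri_lower + t
        bhi = tb.tri_upper + t
        brute = {(i, j)
                 for i in range(a.n_faces) for j in range(b.n_faces)
                 if np.all(ta.tri_upper[i] >= blo[j])
                 and np.all(ta.tri_lower[i] <= bhi[j])}
        # never misses a true overlap; extras only within the fp guard band
        assert pairs >= brute
        for (i, j) in pairs - brute:
            gap = np.maximum(blo[j] - ta.tri_upper[i],
                             ta.tri_lower[i] - bhi[j]).max()
            assert gap < 1e-9


class TestTriTri:
    def test_crossing_triangles_segment(self):
        t1 = np.array([[0, -1, 0], [0, 1, 0], [0, 0, 2]], float)
        t2 = np.array([[-1, 0, 1], [1, 0, 1], [0, 0, -1]], float)
        seg = tri_tri_segment(t1, t2)
        assert seg is not None
        for p in seg:
            assert abs(p[0]) < 1e-12 and abs(p[1]) < 1e-12

    def test_disjoint_triangles_none(self):
        t1 = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        t2 = t1 + np.array([0, 0, 1.0])
        assert tri_tri_segment(t1, t2) is None

    def test_batch_matches_scalar(self, rng):
        hits = 0
        for _ in range(200):
            t1 = rng.normal(size=(3, 3))
            t2 = rng.normal(size=(3, 3)) * 0.8
            scalar = tri_tri_segment(t1, t2)
            p0, p1, idx = tri_tri_segments_batch(t1[None], t2[None])
            if scalar is None:
                assert len(idx) == 0
            else:
                hits += 1
                assert len(idx) == 1
                ends = {tuple(np.round(p, 9)) for p in (p0[0], p1[0])}
                expect = {tuple(np.round(p, 9)) for p in scalar}
                assert ends == expect
        assert hits > 20   # the sample must actually exercise intersections

    def test_point_triangle_closest_matches_constrained_oracle(self, rng):
        from scipy.optimize import minimize
        tris = rng.normal(size=(6, 3, 3))
        pts = rng.normal(size=(5, 3))
        dist, closest = point_triangle_closest(pts, tris)
        for pi in range(len(pts)):
            for ti in range(len(tris)):
                A, B, C = tris[ti]

                def f(uv):
                    q = A + uv[0] * (B - A) + uv[1] * (C - A)
                    return np.sum((q - pts[pi]) ** 2)

                best = min(
                    minimize(f, s, method="SLSQP",
                             bounds=[(0, 1), (0, 1)],
                             constraints=[{"type": "ineq",
                                           "fun": lambda uv: 1 - uv[0] - uv[1]}],
                             options={"ftol": 1e-14, "maxiter": 200}).fun
                    for s in ([0.3, 0.3], [0.9, 0.05], [0.05, 0.9], [0.0, 0.0]))
                assert dist[pi, ti] == pytest.approx(np.sqrt(best), abs=1e-6)


class TestMeshContacts:
    def test_two_icospheres_overlap_depth(self):
        a = make_icosphere(0.1, 3)
        b = make_icosphere(0.1, 3)
        be = MeshContactBackend(a, b)
        ps = be.contacts((I3, ZERO), (I3, np.array([0.19, 0, 0])))
        assert len(ps) == 1
        # analytic sphere-sphere overlap: 0.2 - 0.19 = 0.01
        assert ps[0].delta == pytest.approx(0.01, abs=5e-4)
        assert ps[0].normal @ np.array([1.0, 0, 0]) > np.cos(np.radians(2))

    def test_disjoint_meshes_no_patches(self):
        a = make_icosphere(0.1, 2)
        b = make_icosphere(0.1, 2)
        be = MeshContactBackend(a, b)
        assert be.contacts((I3, ZERO), (I3, np.array([0.25, 0, 0]))) == []

    def test_sphere_on_dense_plane_depth_and_normal(self):
        plane = plane_mesh(n=80)
        s = make_icosphere(0.1, 4)
        be = MeshContactBackend(plane, s)
        ps = be.contacts((I3, ZERO), (I3, np.array([0, 0, 0.098])))
        assert len(ps) == 1
        assert ps[0].delta == pytest.approx(0.002, abs=1.5e-4)
        assert ps[0].normal @ np.array([0, 0, 1.0]) > np.cos(np.radians(1))

    def test_contour_is_closed_polyline(self):
        plane = plane_mesh(n=60)
        s = make_icosphere(0.1, 3)
        be = MeshContactBackend(plane, s)
        ps = be.contacts((I3, ZERO), (I3, np.array([0, 0, 0.097])))
        contour = ps[0].contour[0]
        assert np.linalg.norm(contour[0] - contour[-1]) < 1e-6

    def test_frame_objectivity(self):
        from pftwin.quat import quat_from_axis_angle, rotmat
        a = make_icosphere(0.1, 2)
        b = make_icosphere(0.1, 2)
        be = MeshContactBackend(a, b)
        d0 = be.contacts((I3, ZERO), (I3, np.array([0.19, 0, 0])),
                         track_episodes=False)[0].delta
        R = rotmat(quat_from_axis_angle([0.3, 1.0, -0.2], 0.8))
        t = np.array([0.5, -0.2, 0.3])
        d1 = be.contacts((R, t), (R, R @ np.array([0.19, 0, 0]) + t),
                         track_episodes=False)[0].delta
        assert d1 == pytest.approx(d0, abs=1e-10)


class TestClosestPoint:
    def test_flat_surface_projection(self):
        s = PolynomialSurface(order=2, coefficients=np.zeros(6),
                              fit_domain=((-1, 1), (-1, 1)))
        r = closest_point(s, [0.3, -0.2, 0.5])
        assert np.allclose(r.point, [0.3, -0.2, 0.0], atol=1e-12)
        assert r.distance == pytest.approx(0.5, abs=1e-12)

    def test_paraboloid_apex_attraction(self):
        # z = x^2: centers on the axis below the focal height project to apex
        coefs = np.zeros(6)
        coefs[3] = 1.0   # x^2 term in graded order [1, x, y, x2, xy, y2]
        s = PolynomialSurface(order=2, coefficients=coefs,
                              fit_domain=((-1, 1), (-1, 1)))
        r = closest_point(s, [0.0, 0.0, 0.3])
        assert np.allclose(r.point, [0, 0, 0], atol=1e-8)

    def test_random_quintic_matches_grid_refine_oracle(self, rng):
        from scipy.optimize import minimize
        coefs = 0.3 * rng.normal(size=n_coefficients(5))
        s = PolynomialSurface(order=5, coefficients=coefs,
                              fit_domain=((-1, 1), (-1, 1)))
        xs = np.linspace(-1, 1, 200)
        X, Y = np.meshgrid(xs, xs)
        Z = s.evaluate(X, Y)
        for _ in range(15):
            c = rng.uniform(-0.8, 0.8, 3)
            r = closest_point(s, c)
            d2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
            k = np.unravel_index(np.argmin(d2), d2.shape)
            f = lambda p: ((p[0] - c[0]) ** 2 + (p[1] - c[1]) ** 2
                           + (float(s.evaluate(p[0], p[1])) - c[2]) ** 2)
            o = minimize(f, [X[k], Y[k]], method="Nelder-Mead",
                         options={"xatol": 1e-12, "fatol": 1e-24})
            assert r.distance == pytest.approx(np.sqrt(o.fun), abs=1e-6)

    def test_stationarity_residual_small(self, rng):
        coefs = 0.2 * rng.normal(size=n_coefficients(4))
        s = PolynomialSurface(order=4, coefficients=coefs,
                              fit_domain=((-1, 1), (-1, 1)))
        r = closest_point(s, [0.2, 0.1, 0.5])
        assert r.residual < 1e-10


class TestSphereSurfaceContact:
    def setup_method(self):
        self.plane = PolynomialSurface(order=2, coefficients=np.zeros(6),
                                       fit_domain=((-1, 1), (-1, 1)))
        self.sphere = SpherePrimitive(radius=0.015)

    def test_gap_means_no_contact(self):
        p = sphere_surface_contact(self.sphere, (I3, [0, 0, 0.016]),
                                   self.plane, (I3, ZERO))
        assert p is None

    def test_plane_contact_depth_and_normal(self):
        p = sphere_surface_contact(self.sphere, (I3, [0, 0, 0.013]),
                                   self.plane, (I3, ZERO))
        assert p.delta == pytest.approx(0.002, abs=1e-12)
        assert np.allclose(p.normal, [0, 0, 1])

    def test_center_below_surface_is_deep_penetration(self):
        p = sphere_surface_contact(self.sphere, (I3, [0, 0, -0.004]),
                                   self.plane, (I3, ZERO))
        assert p.deep
        assert p.delta == pytest.approx(0.015 + 0.004, abs=1e-12)

    def test_delta_continuous_across_ridge_sweep(self, scenario):
        from pftwin.bench import fit_femur_surface
        surf = fit_femur_surface(scenario, 5)
        g = scenario.groove
        ys = np.linspace(-1.25 * g.groove_halfwidth,
                         1.25 * g.groove_halfwidth, 400)
        deltas = []
        for y in ys:
            z = float(g.height(0.0, y)) + 0.0145
            p = sphere_surface_contact(SpherePrimitive(radius=0.015),
                                       (I3, [0.0, y, z]), surf, (I3, ZERO))
            deltas.append(p.delta if p else 0.0)
        deltas = np.asarray(deltas)
        assert deltas.max() > 0
        assert np.abs(np.diff(deltas)).max() < 5e-4   # no jumps

    def test_frame_objectivity_of_delta(self):
        from pftwin.quat import quat_from_axis_angle, rotmat
        R = rotmat(quat_from_axis_angle([1, 2, 3], 1.1))
        t = np.array([0.3, -0.1, 0.2])
        p0 = sphere_surface_contact(self.sphere, (I3, [0.05, 0.02, 0.0141]),
                                    self.plane, (I3, ZERO))
        c2 = R @ np.array([0.05, 0.02, 0.0141]) + t
        p1 = sphere_surface_contact(self.sphere, (R, c2), self.plane, (R, t))
        assert p1.delta == pytest.approx(p0.delta, abs=1e-10)


class TestEpisodes:
    def test_delta_dot0_latched_once_per_episode(self):
        tr = EpisodeTracker()
        mk = lambda dd: [ContactPatch(point=np.zeros(3),
                                      normal=np.array([0, 0, 1.0]),
                                      delta=1e-4, delta_dot=dd)]
        p1 = tr.update(mk(0.25), t=0.0)
        assert p1[0].delta_dot0 == 0.25
        p2 = tr.update(mk(-0.10), t=0.001)
        assert p2[0].delta_dot0 == 0.25           # held until separation
        tr.update([], t=0.002)                    # separation closes it
        p3 = tr.update(mk(0.08), t=0.003)
        assert p3[0].delta_dot0 == 0.08           # fresh episode re-latches

    def test_grazing_start_disables_dissipation(self):
        tr = EpisodeTracker()
        p = tr.update([ContactPatch(point=np.zeros(3),
                                    normal=np.array([0, 0, 1.0]),
                                    delta=1e-5, delta_dot=-0.02)], t=0.0)
        assert p[0].delta_dot0 is None
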