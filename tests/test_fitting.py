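import numpy as np
import pytest

import curvecage as cc
from curvecage.curves import ConstraintPointSet
from curvecage.errors import ConstraintError, GeometryError, ParameterError
from curvecage.fitting import (
    FittingParameters,
    closest_point_on_mesh,
    closest_points_on_mesh,
    fit_template_to_curves,
    graph_laplacian,
    solve_cage_update,
)

from conftest import surface_constraint_points


def random_blob_mesh(seed=0, subdiv=2):
    """Random watertight 200-ish triangle mesh (bumpy sphere)."""
    rng = np.random.default_rng(seed)
    s = cc.icosphere(10.0, subdiv)
    r = 1.0 + 0.25 * np.sin(3 * s.vertices[:, 0]) * np.cos(2 * s.vertices[:, 1])
    return cc.TriangleMesh(s.vertices * r[:, None], s.triangles)


def brute_force_closest(mesh, q):
    """Independent oracle: per-triangle closest point via plane projection
    and edge clamping, scanning every triangle."""
    best_d2, best_p = np.inf, None
    for tri in mesh.triangles:
        a, b, c = mesh.vertices[tri]
        n = np.cross(b - a, c - a)
        n = n / np.linalg.norm(n)
        p = q - np.dot(q - a, n) * n
        # inside test via barycentric areas
        area = np.linalg.norm(np.cross(b - a, c - a))
        w0 = np.dot(np.cross(b - p, c - p), n) / area
        w1 = np.dot(np.cross(c - p, a - p), n) / area
        w2 = np.dot(np.cross(a - p, b - p), n) / area
        candidates = []
        if w0 >= 0 and w1 >= 0 and w2 >= 0:
            candidates.append(p)
        for e0, e1 in ((a, b), (b, c), (c, a)):
            t = np.clip(np.dot(q - e0, e1 - e0) / np.dot(e1 - e0, e1 - e0), 0, 1)
            candidates.append(e0 + t * (e1 - e0))
        for cand in candidates:
            d2 = float(np.dot(q - cand, q - cand))
            if d2 < best_d2:
                best_d2, best_p = d2, cand
    return best_p, best_d2


class TestClosestPoint:
    def test_vertex_coincident(self):
        m = random_blob_mesh()
        q = m.vertices[17]
        tri, bary, foot = closest_point_on_mesh(m, q)
        np.testing.assert_allclose(foot, q, atol=1e-12)
        assert bary.max() == pytest.approx(1.0, abs=1e-9)

    def test_face_centroid_normal(self):
        v = np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0], [0.6, 0.6, -2]], dtype=float)
        t = np.array([[0, 1, 2], [0, 3, 1], [1, 3, 2], [0, 2, 3]])
        m = cc.TriangleMesh(v, t)
        centroid = v[:3].mean(axis=0)
        q = centroid + np.array([0, 0, 1.0])  # along +z normal of triangle 0
        tri, bary, foot = closest_point_on_mesh(m, q)
        assert tri == 0
        np.testing.assert_allclose(foot, centroid, atol=1e-12)
        np.testing.assert_allclose(bary, 1 / 3, atol=1e-9)

    def test_oracle_equivalence_100_random_queries(self):
        m = random_blob_mesh(seed=3)
        assert 150 <= len(m.triangles) <= 400
        rng = np.random.default_rng(7)
        qs = rng.uniform(-14, 14, size=(100, 3))
        assoc = closest_points_on_mesh(m, qs)
        for k in range(100):
            foot_o, d2_o = brute_force_closest(m, qs[k])
            d2 = float(np.dot(qs[k] - assoc.footpoints[k], qs[k] - assoc.footpoints[k]))
            assert abs(np.sqrt(d2) - np.sqrt(d2_o)) < 1e-9
            np.testing.assert_allclose(assoc.footpoints[k], foot_o, atol=1e-7)

    def test_barycentric_validity(self):
        m = random_blob_mesh(seed=5)
        rng = np.random.default_rng(11)
        qs = rng.uniform(-12, 12, size=(40, 3))
        assoc = closest_points_on_mesh(m, qs)
        assert assoc.barycentric.min() >= 0
        np.testing.assert_allclose(assoc.barycentric.sum(axis=1), 1.0, atol=1e-12)
        recon = np.einsum(
            "kj,kji->ki", assoc.barycentric, m.vertices[m.triangles[assoc.triangle_indices]]
        )
        np.testing.assert_allclose(recon, assoc.footpoints, atol=1e-12)

    def test_degenerate_triangle_rejected(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 0, 1]], dtype=float)
        t = np.array([[0, 1, 2], [0, 1, 3], [1, 2, 3], [0, 3, 2]])
        m = cc.TriangleMesh(v, t)
        with pytest.raises(GeometryError, match="triangle 0"):
            closest_point_on_mesh(m, np.array([0.5, 0.5, 0.5]))


class TestGraphLaplacian:
    def test_cube_valence(self, unit_cube_cage):
        L = graph_laplacian(unit_cube_cage).toarray()
        for j in range(8):
            off = np.delete(L[j], j)
            assert L[j, j] == pytest.approx(1.0)
            assert sorted(off[off != 0]) == pytest.approx([-1 / 3] * 3)

    def test_row_sums_zero(self, sphere_template):
        L = graph_laplacian(sphere_template.cage)
        np.testing.assert_allclose(np.asarray(L.sum(axis=1)).ravel(), 0.0, atol=1e-12)

    def test_translation_invariance(self, unit_cube_cage):
        L = graph_laplacian(unit_cube_cage)
        c = unit_cube_cage.vertices
        np.testing.assert_allclose(L @ c, L @ (c + [5.0, -3.0, 2.0]), atol=1e-12)


def tiny_template():
    """Cube cage + 4-vertex mesh with hand-set binding weights."""
    cage = cc.box_lattice_cage([0, 0, 0], [1, 1, 1], (2, 2, 2))
    v = np.array(
        [[0.5, 0.5, 0.5], [0.6, 0.5, 0.5], [0.5, 0.6, 0.5], [0.5, 0.5, 0.6]]
    )
    t = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    mesh = cc.TriangleMesh(v, t)
    rng = np.random.default_rng(42)
    w = rng.uniform(0.05, 1.0, size=(4, 8))
    w /= w.sum(axis=1, keepdims=True)
    return cc.Template(mesh, cage, cc.HarmonicBinding(w))


class TestSolveCageUpdate:
    def test_fixed_point(self, sphere_template_coarse):
        t = sphere_template_coarse
        mesh = cc.deform_mesh(t, t.cage.vertices)
        cps = surface_constraint_points(mesh, n=32)
        assoc = closest_points_on_mesh(mesh, cps.points)
        out = solve_cage_update(t, t.cage.vertices, assoc, cps, FittingParameters())
        np.testing.assert_allclose(out, t.cage.vertices, atol=1e-9)

    def test_huge_beta_freezes_cage(self, sphere_template_coarse):
        t = sphere_template_coarse
        mesh = cc.deform_mesh(t, t.cage.vertices)
        cps = ConstraintPointSet(mesh.vertices[:20] * 1.3)
        assoc = closest_points_on_mesh(mesh, cps.points)
        out = solve_cage_update(
            t, t.cage.vertices, assoc, cps, FittingParameters(beta=1e9)
        )
        assert np.abs(out - t.cage.vertices).max() < 1e-6

    def test_dense_normal_equations_oracle(self):
        # independent oracle: assemble the full least-squares system densely
        # with explicit loops and solve with numpy
        tpl = tiny_template()
        params = FittingParameters(alpha=1.0, beta=0.7, gamma=2.5)
        mesh = cc.deform_mesh(tpl, tpl.cage.vertices)
        targets = ConstraintPointSet(np.array([[0.8, 0.6, 0.55], [0.45, 0.35, 0.7]]))
        assoc = closest_points_on_mesh(mesh, targets.points)

        n_c = 8
        L = graph_laplacian(tpl.cage).toarray()
        B = np.zeros((len(targets), n_c))
        for k in range(len(targets)):
            tri = tpl.mesh.triangles[assoc.triangle_indices[k]]
            for corner, vi in enumerate(tri):
                for j in range(n_c):
                    B[k, j] += assoc.barycentric[k, corner] * tpl.binding.weights[vi, j]
        M = params.alpha * B.T @ B + params.beta * np.eye(n_c) + params.gamma * L.T @ L
        c0 = tpl.cage.vertices
        oracle = np.empty_like(c0)
        for ax in range(3):
            rhs = (
                params.alpha * B.T @ targets.points[:, ax]
                + params.beta * c0[:, ax]
                + params.gamma * L.T @ L @ c0[:, ax]
            )
            oracle[:, ax] = np.linalg.solve(M, rhs)
        got = solve_cage_update(tpl, c0, assoc, targets, params)
        np.testing.assert_allclose(got, oracle, atol=1e-9)

    def test_empty_constraints_rejected(self, sphere_template_coarse):
        t = sphere_template_coarse
        mesh = cc.deform_mesh(t, t.cage.vertices)
        cps = ConstraintPointSet(mesh.vertices[:1])
        assoc = closest_points_on_mesh(mesh, cps.points)
        with pytest.raises(ConstraintError):
            solve_cage_update(
                t, t.cage.vertices, assoc, ConstraintPointSet(np.zeros((0, 3))),
                FittingParameters(),
            )

    def test_nonfinite_rejected(self, sphere_template_coarse):
        t = sphere_template_coarse
        mesh = cc.deform_mesh(t, t.cage.vertices)
        bad = ConstraintPointSet(np.array([[np.nan, 0, 0]]))
        assoc = closest_points_on_mesh(mesh, np.array([[0.0, 0, 0]]))
        with pytest.raises(ParameterError):
            solve_cage_update(t, t.cage.vertices, assoc, bad, FittingParameters())


class TestFittingParameters:
    def test_defaults_match_printed_values(self):
        p = FittingParameters()
        assert (p.alpha, p.beta, p.gamma, p.iterations) == (1.0, 1.0, 5.0, 20)

    def test_alpha_positive_required(self):
        with pytest.raises(ParameterError):
            FittingParameters(alpha=0.0)


class TestFitTemplate:
    def test_fixed_point_full_run(self, sphere_template):
        t = sphere_template
        state = cc.FrameState(0, t.cage.vertices.copy())
        mesh = cc.deform_mesh(t, state.cage_vertices)
        cps = surface_constraint_points(mesh, n=64)
        out, diag = fit_template_to_curves(t, state, cps)
        assert np.abs(out.cage_vertices - state.cage_vertices).max() < 1e-6
        assert diag.final_mean_residual < 1e-6

    def test_ellipsoid_recovery(self, sphere_template):
        t = sphere_template
        target = cc.TriangleMesh(
            t.mesh.vertices * np.array([24.0, 20.0, 16.0]) / 20.0, t.mesh.triangles
        )
        cps = surface_constraint_points(target, n=64)
        state = cc.FrameState(0, t.cage.vertices.copy())
        out, diag = fit_template_to_curves(t, state, cps)
        assert diag.final_mean_residual < 0.1 * diag.mean_residuals[0]
        assert diag.converged

    def test_objective_descends_every_iteration(self, sphere_template):
        t = sphere_template
        target = cc.TriangleMesh(t.mesh.vertices * 1.15, t.mesh.triangles)
        cps = surface_constraint_points(target, n=48)
        state = cc.FrameState(0, t.cage.vertices.copy())
        _, diag = fit_template_to_curves(t, state, cps)
        for before, after in zip(diag.objective_before, diag.objective_after):
            assert after <= before + 1e-9

    def test_determinism_bit_identical(self, sphere_template):
        t = sphere_template
        target = cc.TriangleMesh(t.mesh.vertices * 1.1, t.mesh.triangles)
        cps = surface_constraint_points(target, n=32)
        state = cc.FrameState(0, t.cage.vertices.copy())
        out1, d1 = fit_template_to_curves(t, state, cps)
        out2, d2 = fit_template_to_curves(t, state, cps)
        np.testing.assert_array_equal(out1.cage_vertices, out2.cage_vertices)
        assert d1.mean_residuals == d2.mean_residuals
        assert d1.max_residuals == d2.max_residuals

    def test_rigid_equivariance(self, sphere_template_coarse):
        t = sphere_template_coarse
        target = cc.TriangleMesh(
            t.mesh.vertices * np.array([1.15, 1.0, 0.9]), t.mesh.triangles
        )
        cps = surface_constraint_points(target, n=32)
        state = cc.FrameState(0, t.cage.vertices.copy())
        out, _ = fit_template_to_curves(t, state, cps, FittingParameters(iterations=5))

        R = cc.SimilarityTransform.from_axis_angle((1, 1, 0), 0.6, 1.0, (7.0, -3.0, 2.0))
        t_r = cc.Template(
            t.mesh.with_vertices(R.apply(t.mesh.vertices)),
            t.cage.with_vertices(R.apply(t.cage.vertices)),
            t.binding,
        )
        cps_r = ConstraintPointSet(R.apply(cps.points))
        state_r = cc.FrameState(0, t_r.cage.vertices.copy())
        out_r, _ = fit_template_to_curves(
            t_r, state_r, cps_r, FittingParameters(iterations=5)
        )
        np.testing.assert_allclose(
            out_r.cage_vertices, R.apply(out.cage_vertices), atol=1e-6
        )

    def test_early_stop_option(self, sphere_template_coarse):
        t = sphere_template_coarse
        mesh = cc.deform_mesh(t, t.cage.vertices)
        cps = surface_constraint_points(mesh, n=32)
        state = cc.FrameState(0, t.cage.vertices.copy())
        _, diag = fit_template_to_curves(
            t, state, cps, FittingParameters(early_stop_tol=1e-9)
        )
        assert len(diag.mean_residuals) < 20

    def test_empty_constraints(self, sphere_template_coarse):
        state = cc.FrameState(0, sphere_template_coarse.cage.vertices.copy())
        with pytest.raises(ConstraintError):
            fit_template_to_curves(
                sphere_template_coarse, state, ConstraintPointSet(np.zeros((0, 3)))
            )

    def test_data_term_scales_with_sampling_density(self, sphere_template_coarse):
        # Eq-3 terms are unnormalized: halving the resample interval roughly
        # doubles the data term at the first iteration
        t = sphere_template_coarse
        target = cc.TriangleMesh(t.mesh.vertices * 1.2, t.mesh.triangles)
        state = cc.FrameState(0, t.cage.vertices.copy())
        c1 = surface_constraint_points(target, n=32)
        c2 = surface_constraint_points(target, n=64)
        _, d1 = fit_template_to_curves(t, state, c1, FittingParameters(iterations=1))
        _, d2 = fit_template_to_curves(t, state, c2, FittingParameters(iterations=1))
        ratio = d2.objective_before[0] / d1.objective_before[0]
        assert 1.6 < ratio < 2.4
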