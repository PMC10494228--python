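"""Branching/seam decomposition and cone-topography extraction."""

import numpy as np
import pytest

import omegacp as o
from omegacp.topography import (
    cnm2_field,
    hessian_cnm2,
    split_branching_seam,
)


class TestHessian:
    def test_exact_on_quadratic(self):
        field = lambda pts: -(2.0 * pts[:, 0] ** 2 + 0.7 * pts[:, 1] ** 2)
        h = hessian_cnm2(field, np.zeros(2), 1e-3)
        np.testing.assert_allclose(h, np.diag([-4.0, -1.4]), atol=1e-8)

    def test_zero_on_constant(self):
        field = lambda pts: np.full(len(pts), 2.5)
        np.testing.assert_allclose(hessian_cnm2(field, np.zeros(3), 1e-2), 0.0)

    def test_second_order_convergence_on_quartic(self):
        field = lambda pts: pts[:, 0] ** 4 + pts[:, 0] ** 2 * pts[:, 1] ** 2
        point = np.array([0.4, 0.3])
        exact = np.array(
            [
                [12 * 0.4**2 + 2 * 0.3**2, 4 * 0.4 * 0.3],
                [4 * 0.4 * 0.3, 2 * 0.4**2],
            ]
        )
        errs = [
            np.abs(hessian_cnm2(field, point, s) - exact).max() for s in (0.1, 0.05)
        ]
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.25)

    def test_invalid_step(self):
        with pytest.raises(ValueError):
            hessian_cnm2(lambda p: p[:, 0], np.zeros(1), 0.0)


class TestSplitBranchingSeam:
    def test_two_state_in_five_coordinates(self):
        split = split_branching_seam(np.diag([-0.5, -0.5, 0.0, 0.0, 0.0]))
        assert split.branching_dim == 2
        assert split.seam_values.size == 3
        b, s = split.branching_vectors, split.seam_vectors
        np.testing.assert_allclose(b.T @ b, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(s.T @ s, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(b.T @ s, 0.0, atol=1e-12)

    @pytest.mark.parametrize(
        "n_states, dim, rank",
        [(2, 2, 2), (2, 4, 1), (2, 8, 2), (3, 5, 4), (3, 7, 5), (3, 8, 3)],
    )
    def test_rank_recovered_from_analytic_hessians(self, n_states, dim, rank):
        m = o.random_linear_vibronic(n_states, dim, rank, seed=rank + 10 * dim)
        assert split_branching_seam(m.cnm2_hessian()).branching_dim == rank

    def test_threshold_robust_on_noiseless_models(self):
        # fixture seed chosen so every branching eigenvalue exceeds 10% of
        # the largest — the precondition for stability up to threshold 1e-1
        m = o.random_linear_vibronic(3, 6, 4, seed=6)
        h = m.cnm2_hessian()
        dims = {
            split_branching_seam(h, relative_threshold=t).branching_dim
            for t in (1e-3, 1e-2, 1e-1)
        }
        assert dims == {4}

    def test_tiny_noise_below_threshold_is_seam(self):
        h = np.diag([-1.0, -1e-5, -1e-6])
        split = split_branching_seam(h, relative_threshold=1e-2)
        assert split.branching_dim == 1

    def test_zero_matrix_gives_branching_dim_zero(self):
        assert split_branching_seam(np.zeros((4, 4))).branching_dim == 0

    def test_deterministic_sign_convention(self):
        h = np.array([[-1.0, 0.3], [0.3, -0.5]])
        split = split_branching_seam(h)
        for k in range(2):
            v = split.branching_vectors[:, k]
            assert v[np.argmax(np.abs(v))] > 0
        # identical input, identical output
        again = split_branching_seam(h)
        np.testing.assert_array_equal(
            split.branching_vectors, again.branching_vectors
        )


class TestConeParameters:
    def test_fig1_analytic_recovery(self, fig1_model):
        rep = o.cone_parameters(fig1_model, [0.0, 0.0])
        assert rep.branching_dim == 2
        assert rep.g_norm == pytest.approx(0.5, abs=1e-7)
        assert rep.h_norm == pytest.approx(0.5, abs=1e-7)
        assert rep.s_x == pytest.approx(0.25, abs=1e-9)
        assert rep.s_y == pytest.approx(0.1, abs=1e-9)

    def test_ethylene_like_parameters_recovered(self):
        # asymmetric, tilted cone with realistic magnitudes (E_h/Å scale)
        m = o.first_order_two_state(0.213, 0.125, -0.130, -0.046)
        rep = o.cone_parameters(m, [0.0, 0.0])
        assert rep.g_norm == pytest.approx(0.213, rel=1e-6)
        assert rep.h_norm == pytest.approx(0.125, rel=1e-6)
        assert rep.s_x == pytest.approx(-0.130, abs=1e-8)
        assert rep.s_y == pytest.approx(-0.046, abs=1e-8)

    def test_untilted_symmetric_cone_has_zero_tilt(self):
        m = o.first_order_two_state(0.342, 0.342, 0.0, 0.0)
        rep = o.cone_parameters(m, [0.0, 0.0])
        assert rep.g_norm == pytest.approx(0.342, rel=1e-6)
        assert rep.h_norm == pytest.approx(0.342, rel=1e-6)
        assert abs(rep.s_x) < 1e-8 and abs(rep.s_y) < 1e-8

    def test_parameter_recovery_on_random_analytic_models(self):
        """(g̃, h̃, s_x, s_y) recovered to ≤1e−6 over random two-state cones."""
        rng = np.random.default_rng(2024)
        for _ in range(50):
            g, h = rng.uniform(0.05, 0.6, size=2)
            sx, sy = rng.uniform(-0.3, 0.3, size=2)
            m = o.first_order_two_state(g, h, sx, sy)
            rep = o.cone_parameters(m, [0.0, 0.0])
            want_g, want_h = max(g, h), min(g, h)
            want_sx, want_sy = (sx, sy) if g >= h else (sy, sx)
            if abs(g - h) <= 0.01 * max(g, h):
                # symmetric cone: x/y assignment canonicalized to the axes
                want_sx, want_sy = sx, sy
            assert rep.g_norm == pytest.approx(want_g, rel=1e-6, abs=1e-8)
            assert rep.h_norm == pytest.approx(want_h, rel=1e-6, abs=1e-8)
            assert rep.s_x == pytest.approx(want_sx, rel=1e-6, abs=1e-6)
            assert rep.s_y == pytest.approx(want_sy, rel=1e-6, abs=1e-6)

    def test_parameter_recovery_on_surrogates(self, raw_descriptor, fixed_policy):
        """≤2% relative recovery from KRR surrogates trained on 2000 points."""
        for g, h, sx, sy, seed in [
            (0.213, 0.125, -0.130, -0.046, 1),
            (0.45, 0.3, 0.2, -0.15, 2),
        ]:
            m = o.first_order_two_state(g, h, sx, sy)
            coords = o.latin_hypercube(2, 2000, (-0.25, 0.25), seed=seed)
            ens = o.fit_ensemble(
                o.make_dataset(m, coords), raw_descriptor, "omega_cp", fixed_policy
            )
            rep = o.cone_parameters(ens, [0.0, 0.0])
            assert rep.g_norm == pytest.approx(g, rel=0.02)
            assert rep.h_norm == pytest.approx(h, rel=0.02)
            assert rep.s_x == pytest.approx(sx, rel=0.02)
            assert rep.s_y == pytest.approx(sy, rel=0.02)

    def test_unsupported_topology_raises(self):
        m3 = o.random_linear_vibronic(3, 7, 5, seed=11)
        with pytest.raises(ValueError, match="branching dimension 5"):
            o.cone_parameters(m3, np.zeros(7))

    def test_report_table_and_dict(self, fig1_model):
        rep = o.cone_parameters(
            fig1_model, [0.0, 0.0], reference_branching=np.eye(2)
        )
        text = rep.table()
        assert "g~" in text and "theta_x" in text
        d = rep.as_dict()
        assert d["branching_dim"] == 2
        np.testing.assert_allclose(d["principal_angles_deg"], 0.0, atol=1e-6)


class TestOrthogonalizeGH:
    def test_orthogonal_input_unchanged_up_to_ordering(self):
        g = np.array([0.4, 0.0, 0.0])
        h = np.array([0.0, 0.2, 0.0])
        x, y, ng, nh = o.orthogonalize_gh(g, h)
        assert ng == pytest.approx(0.4) and nh == pytest.approx(0.2)
        np.testing.assert_allclose(np.abs(x), [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(np.abs(y), [0, 1, 0], atol=1e-12)

    def test_parallel_vectors_degenerate_limit(self):
        g = np.array([1.0, 1.0]) / np.sqrt(2)
        x, y, ng, nh = o.orthogonalize_gh(g, g)
        assert nh < 1e-12 and ng == pytest.approx(np.sqrt(2.0))

    def test_random_pairs_orthogonal_and_span_preserved(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            g, h = rng.normal(size=(2, 4))
            x, y, ng, nh = o.orthogonalize_gh(g, h)
            assert abs(x @ y) < 1e-10
            assert ng >= nh
            # span preserved: original vectors lie in span(x, y)
            basis = np.column_stack([x, y])
            for v in (g, h):
                residual = v - basis @ (basis.T @ v)
                np.testing.assert_allclose(residual, 0.0, atol=1e-10)

    def test_double_zero_rejected(self):
        with pytest.raises(ValueError):
            o.orthogonalize_gh(np.zeros(3), np.zeros(3))


class TestPrincipalAngles:
    def test_identical_and_orthogonal_subspaces(self):
        a = np.eye(4)[:, :2]
        b = np.eye(4)[:, 2:]
        np.testing.assert_allclose(o.principal_angles(a, a), 0.0, atol=1e-10)
        np.testing.assert_allclose(o.principal_angles(a, b), 90.0, atol=1e-10)

    def test_in_plane_rotation_leaves_subspace_fixed(self):
        a = np.eye(3)[:, :2]
        th = np.radians(10.0)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        np.testing.assert_allclose(o.principal_angles(a, a @ rot), 0.0, atol=1e-8)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            o.principal_angles(np.eye(3)[:, :1], np.eye(4)[:, :1])


class TestGapScanAndMECI:
    def test_analytic_scan_closes_at_origin(self, fig1_model):
        xline = np.column_stack([np.linspace(-0.25, 0.25, 101), np.zeros(101)])
        scan = o.gap_scan(fig1_model, xline)
        assert scan.min_gap == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(scan.min_gap_point, [0.0, 0.0], atol=1e-12)
        assert scan.energies.shape == (101, 2)

    def test_meci_found_from_displaced_start(self, fig1_model):
        res = o.locate_meci(fig1_model, [0.1, 0.1])
        assert res.converged
        np.testing.assert_allclose(res.point, [0.0, 0.0], atol=1e-4)

    def test_meci_start_at_intersection(self, fig1_model):
        res = o.locate_meci(fig1_model, [0.0, 0.0])
        assert res.converged and res.gap <= 1e-4

    def test_meci_on_model_with_seam(self):
        # 3 coordinates, branching rank 2 → a 1-D seam through the origin
        m = o.random_linear_vibronic(2, 3, 2, seed=5)
        res = o.locate_meci(m, [0.05, -0.04, 0.08])
        assert res.gap <= 1e-4
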