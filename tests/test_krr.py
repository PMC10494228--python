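"""Kernel ridge regression of ω-CP fields and of raw adiabatic energies."""

import numpy as np
import pytest

import omegacp as o
from omegacp.krr import EnergyPrediction


class TestKernelMatrix:
    def test_closed_form_entries(self):
        a = np.array([[0.0, 0.0]])
        b_rbf = np.array([[np.sqrt(2.0), 0.0]])  # distance ℓ√2 at ℓ=1
        assert o.kernel_matrix("rbf", a, a, 1.0)[0, 0] == pytest.approx(1.0)
        assert o.kernel_matrix("rbf", a, b_rbf, 1.0)[0, 0] == pytest.approx(
            np.exp(-1.0)
        )
        b_mat = np.array([[1.0, 0.0]])  # distance ℓ at ℓ=1
        assert o.kernel_matrix("matern12", a, b_mat, 1.0)[0, 0] == pytest.approx(
            np.exp(-1.0)
        )

    @pytest.mark.parametrize("kind", ["rbf", "matern12"])
    def test_positive_semidefinite_and_symmetric(self, kind):
        rng = np.random.default_rng(17)
        x = rng.normal(size=(40, 3))
        k = o.kernel_matrix(kind, x, x, 0.7)
        np.testing.assert_allclose(k, k.T, atol=1e-14)
        assert np.linalg.eigvalsh(k).min() >= -1e-8

    def test_non_positive_lengthscale_rejected(self):
        with pytest.raises(ValueError):
            o.kernel_matrix("rbf", np.zeros((2, 1)), np.zeros((2, 1)), 0.0)


class TestFit:
    def test_interpolation_at_training_points(self):
        x = np.linspace(-1, 1, 20)[:, None]
        y = x.ravel() ** 2
        m = o.fit(x, y, "rbf", 0.5, 1e-12)
        np.testing.assert_allclose(m.predict(x), y, atol=1e-6)

    def test_constant_targets_and_far_field_decay(self):
        x = np.linspace(0, 1, 10)[:, None]
        m = o.fit(x, np.full(10, 3.0), "rbf", 0.2, 1e-12)
        np.testing.assert_allclose(m.predict(x), 3.0, atol=1e-6)
        far = m.predict(np.array([[50.0]]))
        assert abs(far[0]) < 1e-8  # kernel reach exhausted → decays to 0

    def test_matches_sklearn_kernel_ridge(self):
        """Independent cross-check of the dual solve against scikit-learn."""
        from sklearn.kernel_ridge import KernelRidge

        rng = np.random.default_rng(3)
        x = rng.uniform(-1, 1, size=(50, 2))
        y = np.sin(3 * x[:, 0]) * x[:, 1]
        ls, reg = 0.4, 1e-8
        ours = o.fit(x, y, "rbf", ls, reg)
        theirs = KernelRidge(alpha=reg, kernel="rbf", gamma=1.0 / (2 * ls**2)).fit(x, y)
        q = rng.uniform(-1.2, 1.2, size=(30, 2))
        np.testing.assert_allclose(ours.predict(q), theirs.predict(q), atol=1e-8)

    def test_duplicate_rows_at_zero_reg_raise_actionable_error(self):
        x = np.array([[0.0], [0.0], [1.0]])
        with pytest.raises(np.linalg.LinAlgError, match="regularization"):
            o.fit(x, np.array([0.0, 1.0, 2.0]), "rbf", 1.0, 0.0)


class TestSelectHyperparams:
    def test_single_point_grid_returned(self):
        x = np.linspace(0, 1, 12)[:, None]
        y = x.ravel()
        assert o.select_hyperparams(x, y, [0.5], [1e-8], k_folds=3, seed=0) == (
            0.5,
            1e-8,
        )

    def test_noiseless_linear_target_reaches_tiny_cv_error(self):
        x = np.linspace(-1, 1, 40)[:, None]
        y = 2.0 * x.ravel()
        ls, reg = o.select_hyperparams(
            x, y, [0.1, 0.5, 2.0], [1e-12, 1e-6], k_folds=5, seed=1
        )
        m = o.fit(x, y, "rbf", ls, reg)
        assert np.mean(np.abs(m.predict(x) - y)) < 1e-6

    def test_seeded_folds_are_deterministic(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        pick1 = o.select_hyperparams(x, y, [0.2, 1.0], [1e-10, 1e-6], seed=5)
        pick2 = o.select_hyperparams(x, y, [0.2, 1.0], [1e-10, 1e-6], seed=5)
        assert pick1 == pick2


class TestEnsemble:
    def test_model_counts_match_mode(self, fig1_ensembles):
        # two-state: n = 2 learned quantities in either family
        assert list(fig1_ensembles["omega_cp"].models) == ["omega", "c_0"]
        assert list(fig1_ensembles["direct"].models) == ["E_1", "E_2"]

    def test_three_state_omega_cp_learns_three_fields(self, raw_descriptor):
        m = o.random_linear_vibronic(3, 3, 2, seed=6)
        ds = o.make_dataset(m, o.latin_hypercube(3, 80, (-0.25, 0.25), seed=6))
        pol = o.HyperparamPolicy(kernel="rbf", lengthscale=0.3, regularization=1e-10)
        ens = o.fit_ensemble(ds, raw_descriptor, "omega_cp", pol)
        assert list(ens.models) == ["omega", "c_0", "c_1"]
        ensd = o.fit_ensemble(ds, raw_descriptor, "direct", pol)
        assert list(ensd.models) == ["E_1", "E_2", "E_3"]

    def test_training_points_reproduced(self, fig1_ensembles, fig1_dataset):
        # the smooth omega_cp targets interpolate to the kernel noise floor;
        # the kinked direct targets excite the near-singular modes of the
        # smooth RBF Gram matrix and plateau at a much larger residual
        coords = fig1_dataset.coords_matrix()[:50]
        true = fig1_dataset.energies_matrix()[:50]
        for mode, atol in (("omega_cp", 1e-5), ("direct", 5e-3)):
            pred = o.predict_energies(fig1_ensembles[mode], coords)
            assert isinstance(pred, EnergyPrediction)
            np.testing.assert_allclose(pred.energies, true, atol=atol)

    def test_omega_cp_targets_invariant_to_electronic_basis(self, fig1_model):
        """End-to-end representation invariance of the training targets.

        Energies computed after an orthogonal rotation of the electronic
        basis are the same eigenvalues, so the (ω, c_i) targets coincide;
        cp_invariance_check is the oracle on the underlying matrices.
        """
        rng = np.random.default_rng(31)
        th = rng.uniform(0, 2 * np.pi)
        q = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        for p in rng.uniform(-0.25, 0.25, size=(25, 2)):
            v = fig1_model.potential_matrix(p)
            assert o.cp_invariance_check(v, q)
            rotated_energies = np.sort(np.linalg.eigvalsh(q.T @ v @ q))
            a = o.energies_to_cp(fig1_model.energies(p))
            b = o.energies_to_cp(rotated_energies)
            assert a.omega == pytest.approx(b.omega, abs=1e-12)
            np.testing.assert_allclose(a.coeffs, b.coeffs, atol=1e-12)

    def test_empty_dataset_rejected(self, raw_descriptor):
        ds = o.SampledDataset(samples=[])
        with pytest.raises(ValueError, match="empty"):
            o.fit_ensemble(ds, raw_descriptor)


class TestMAECurve:
    def test_learning_curve_decreases_and_omega_cp_wins(
        self, fig1_model, raw_descriptor, fixed_policy
    ):
        test = o.latin_hypercube(2, 150, (-0.25, 0.25), seed=77)
        kwargs = dict(
            bounds=(-0.25, 0.25), replicates=1, seed=10, policy=fixed_policy
        )
        curves = {
            mode: o.mae_curve(
                fig1_model, raw_descriptor, mode, [40, 160, 640], test, **kwargs
            )
            for mode in ("omega_cp", "direct")
        }
        for mode, tab in curves.items():
            assert list(tab["size"]) == [40, 160, 640]
            # MAE decreases (not strictly) with training-set size
            assert tab["mae_mean"].iloc[-1] <= tab["mae_mean"].iloc[0] * 1.05
        # near the seam the smooth-field family is the more accurate one
        assert (
            curves["omega_cp"]["mae_mean"].iloc[-1]
            < curves["direct"]["mae_mean"].iloc[-1]
        )

    def test_unsorted_sizes_rejected(self, fig1_model, raw_descriptor):
        with pytest.raises(ValueError):
            o.mae_curve(
                fig1_model, raw_descriptor, "omega_cp", [100, 50], np.zeros((5, 2))
            )
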