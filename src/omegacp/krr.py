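"""Kernel ridge regression of the ω-CP fields or of raw adiabatic energies.

Two model families are supported. In ``omega_cp`` mode each training
geometry is transformed to (ω, c_0, ..., c_{n−2}) and one independent
scalar KRR model is fitted per field — n quantities in total; adiabatic
energies are recovered from predictions through the companion matrix. In
``direct`` mode one model is fitted per sorted adiabatic energy level,
which is the conventional approach and serves as the baseline: its targets
are only C⁰ across intersection seams, so it smooths the cone into an
avoided crossing.

The kernel solve is the standard dual form (K + λI)α = y via Cholesky
factorization; hyperparameters come either fixed or from seeded k-fold
cross-validation over log-spaced grids.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist

from .cp import CPRecord, cp_to_energies_projected, energies_to_cp
from .descriptors import DescriptorConfig, featurize_many
from .models import LinearVibronicModel, SampledDataset, latin_hypercube, make_dataset

__all__ = [
    "KernelModel",
    "SurrogateEnsemble",
    "EnergyPrediction",
    "HyperparamPolicy",
    "kernel_matrix",
    "fit",
    "select_hyperparams",
    "fit_ensemble",
    "predict_energies",
    "mae_curve",
]


def kernel_matrix(
    kind: str, x1: np.ndarray, x2: np.ndarray, lengthscale: float
) -> np.ndarray:
    """Covariance matrix between two point sets.

    ``rbf``: exp(−‖a−b‖² / 2ℓ²), infinitely differentiable — suited to the
    smooth ω and c_i fields. ``matern12``: exp(−‖a−b‖/ℓ), C⁰ — the natural
    (but still insufficient) choice when regressing intersecting adiabatic
    surfaces directly.
    """
    if lengthscale <= 0:
        raise ValueError("lengthscale must be positive")
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    if kind == "rbf":
        d2 = cdist(x1, x2, "sqeuclidean")
        return np.exp(-d2 / (2.0 * lengthscale**2))
    if kind == "matern12":
        d = cdist(x1, x2, "euclidean")
        return np.exp(-d / lengthscale)
    raise ValueError(f"unknown kernel kind {kind!r}")


@dataclass(frozen=True)
class KernelModel:
    """One fitted scalar KRR model: dual weights over the training features."""

    kernel: str
    lengthscale: float
    regularization: float
    x_train: np.ndarray
    alpha: np.ndarray
    target_label: str = ""

    def predict(self, x: np.ndarray) -> np.ndarray:
        k = kernel_matrix(self.kernel, np.atleast_2d(x), self.x_train, self.lengthscale)
        return k @ self.alpha


def fit(
    features: np.ndarray,
    targets: np.ndarray,
    kernel: str = "rbf",
    lengthscale: float = 1.0,
    regularization: float = 1e-10,
    target_label: str = "",
) -> KernelModel:
    """Solve (K + λI)α = y by Cholesky factorization."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(targets, dtype=float).ravel()
    if x.shape[0] != y.size or y.size < 2:
        raise ValueError("need matching features/targets with at least two rows")
    if regularization < 0:
        raise ValueError("regularization must be ≥ 0")
    k = kernel_matrix(kernel, x, x, lengthscale)
    k[np.diag_indices_from(k)] += regularization
    try:
        alpha = cho_solve(cho_factor(k, lower=True), y)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "kernel system is singular (duplicate training rows at zero "
            "regularization?); set regularization > 0"
        ) from exc
    return KernelModel(
        kernel=kernel,
        lengthscale=lengthscale,
        regularization=regularization,
        x_train=x,
        alpha=alpha,
        target_label=target_label,
    )


def select_hyperparams(
    features: np.ndarray,
    targets: np.ndarray,
    lengthscale_grid: Sequence[float],
    regularization_grid: Sequence[float],
    kernel: str = "rbf",
    k_folds: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """Seeded k-fold cross-validation grid search minimizing mean MAE.

    Ties are broken toward the larger lengthscale, then the larger
    regularization — the smoother, better-conditioned model.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(targets, dtype=float).ravel()
    if not len(lengthscale_grid) or not len(regularization_grid):
        raise ValueError("hyperparameter grids must be nonempty")
    if k_folds < 2:
        raise ValueError("need at least 2 folds")
    n = x.shape[0]
    if n < k_folds:
        raise ValueError(f"need at least {k_folds} samples for {k_folds}-fold CV")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k_folds)
    best: tuple[float, float, float] | None = None  # (mae, ls, reg)
    for ls, reg in itertools.product(lengthscale_grid, regularization_grid):
        maes = []
        for f in folds:
            train = np.setdiff1d(perm, f, assume_unique=True)
            try:
                m = fit(x[train], y[train], kernel, ls, reg)
            except np.linalg.LinAlgError:
                maes = [np.inf]
                break
            maes.append(float(np.mean(np.abs(m.predict(x[f]) - y[f]))))
        mae = float(np.mean(maes))
        if (
            best is None
            or mae < best[0]
            or (mae == best[0] and (ls, reg) > (best[1], best[2]))
        ):
            best = (mae, float(ls), float(reg))
    return best[1], best[2]


@dataclass(frozen=True)
class HyperparamPolicy:
    """Fixed hyperparameters, or CV grids when the fixed values are None."""

    kernel: str = "rbf"
    lengthscale: float | None = None
    regularization: float | None = None
    lengthscale_grid: tuple[float, ...] = (0.03, 0.1, 0.3, 1.0, 3.0)
    regularization_grid: tuple[float, ...] = (1e-12, 1e-10, 1e-8, 1e-6)
    k_folds: int = 5
    seed: int = 0

    def resolve(self, features: np.ndarray, targets: np.ndarray) -> tuple[float, float]:
        if self.lengthscale is not None and self.regularization is not None:
            return self.lengthscale, self.regularization
        return select_hyperparams(
            features,
            targets,
            self.lengthscale_grid if self.lengthscale is None else (self.lengthscale,),
            self.regularization_grid
            if self.regularization is None
            else (self.regularization,),
            kernel=self.kernel,
            k_folds=self.k_folds,
            seed=self.seed,
        )


@dataclass
class SurrogateEnsemble:
    """One fitted kernel model per learned scalar field.

    ``omega_cp`` mode carries models labeled ``omega, c_0, ..., c_{n−2}``;
    ``direct`` mode carries ``E_1, ..., E_n`` (sorted adiabatic levels).
    """

    mode: str
    n_states: int
    descriptor: DescriptorConfig
    models: dict[str, KernelModel]
    elements: list[str] | None = None

    def __post_init__(self) -> None:
        expected = self.field_labels(self.mode, self.n_states)
        if list(self.models.keys()) != expected:
            raise ValueError(f"expected models for fields {expected}")

    @staticmethod
    def field_labels(mode: str, n_states: int) -> list[str]:
        if mode == "omega_cp":
            return ["omega"] + [f"c_{i}" for i in range(n_states - 1)]
        if mode == "direct":
            return [f"E_{i + 1}" for i in range(n_states)]
        raise ValueError(f"unknown mode {mode!r}")

    def features(self, coords: np.ndarray) -> np.ndarray:
        return featurize_many(self.descriptor, coords, self.elements)

    def predict_fields(self, coords: np.ndarray) -> dict[str, np.ndarray]:
        x = self.features(coords)
        return {label: m.predict(x) for label, m in self.models.items()}


@dataclass(frozen=True)
class EnergyPrediction:
    """Predicted sorted adiabatic energies plus realizability metadata.

    ``complex_flags[i]`` marks query points whose predicted CP coefficients
    had no real spectrum (companion eigenvalues with non-negligible
    imaginary parts, projected to their real parts). Always all-False in
    direct mode.
    """

    energies: np.ndarray
    complex_flags: np.ndarray

    @property
    def gaps(self) -> np.ndarray:
        return np.diff(self.energies, axis=1)


def fit_ensemble(
    dataset: SampledDataset,
    descriptor: DescriptorConfig,
    mode: str = "omega_cp",
    policy: HyperparamPolicy | None = None,
) -> SurrogateEnsemble:
    """Fit one KRR model per learned field from a sampled dataset."""
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    policy = policy or HyperparamPolicy()
    labels = SurrogateEnsemble.field_labels(mode, dataset.n_states)
    x = featurize_many(descriptor, dataset.coords_matrix(), dataset.elements)
    energies = dataset.energies_matrix()
    if mode == "omega_cp":
        records = [energies_to_cp(e) for e in energies]
        targets = np.column_stack(
            [[r.omega for r in records]]
            + [[r.coeffs[i] for r in records] for i in range(dataset.n_states - 1)]
        )
    else:
        targets = energies
    models = {}
    for j, label in enumerate(labels):
        ls, reg = policy.resolve(x, targets[:, j])
        models[label] = fit(x, targets[:, j], policy.kernel, ls, reg, label)
    return SurrogateEnsemble(
        mode=mode,
        n_states=dataset.n_states,
        descriptor=descriptor,
        models=models,
        elements=dataset.elements,
    )


def predict_energies(ensemble: SurrogateEnsemble, coords: np.ndarray) -> EnergyPrediction:
    """Predict sorted adiabatic energies at each coordinate row.

    ω-CP mode assembles a :class:`~omegacp.cp.CPRecord` per point from the
    field predictions and reconstructs energies via the companion matrix;
    direct mode sorts the per-level predictions.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    fields = ensemble.predict_fields(coords)
    m = coords.shape[0]
    n = ensemble.n_states
    out = np.empty((m, n))
    flags = np.zeros(m, dtype=bool)
    if ensemble.mode == "omega_cp":
        omegas = fields["omega"]
        coeff_cols = np.column_stack([fields[f"c_{i}"] for i in range(n - 1)])
        for i in range(m):
            rec = CPRecord(omega=float(omegas[i]), coeffs=coeff_cols[i], n_states=n)
            out[i], flags[i] = cp_to_energies_projected(rec)
    else:
        stacked = np.column_stack([fields[f"E_{i + 1}"] for i in range(n)])
        out = np.sort(stacked, axis=1)
    return EnergyPrediction(energies=out, complex_flags=flags)


def mae_curve(
    model: LinearVibronicModel,
    descriptor: DescriptorConfig,
    mode: str,
    training_sizes: Sequence[int],
    test_coords: np.ndarray,
    bounds: tuple[float, float] = (-0.25, 0.25),
    replicates: int = 1,
    seed: int = 0,
    policy: HyperparamPolicy | None = None,
) -> pd.DataFrame:
    """Learning curve: per-state test MAE versus training-set size.

    For each size a fresh Latin hypercube training set is drawn around the
    intersection, a surrogate fitted, and the mean absolute error per
    adiabatic state measured on the fixed test set; replicates average over
    independent draws.
    """
    sizes = list(training_sizes)
    if sizes != sorted(sizes):
        raise ValueError("training sizes must be ascending")
    test_coords = np.atleast_2d(np.asarray(test_coords, dtype=float))
    if test_coords.shape[0] == 0:
        raise ValueError("test set is empty")
    test_true = np.array([model.energies(r) for r in test_coords])
    rows = []
    for size in sizes:
        per_state = np.zeros(model.n_states)
        for rep in range(replicates):
            sub_seed = (seed * 1_000 + size * 10 + rep) % (2**31 - 1)
            coords = latin_hypercube(model.dim, size, bounds, seed=sub_seed)
            ens = fit_ensemble(
                make_dataset(model, coords), descriptor, mode=mode, policy=policy
            )
            pred = predict_energies(ens, test_coords).energies
            per_state += np.mean(np.abs(pred - test_true), axis=0)
        per_state /= replicates
        rows.append(
            {"size": size, "mode": mode}
            | {f"mae_E_{i + 1}": per_state[i] for i in range(model.n_states)}
            | {"mae_mean": float(per_state.mean())}
        )
    return pd.DataFrame(rows)
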