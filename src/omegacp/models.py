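"""Analytic linear vibronic coupling models and training-set samplers.

A linear vibronic coupling (LVC) model is the minimal analytic potential
exhibiting a conical intersection: the n×n potential matrix is linear in
the nuclear coordinates,

    V(x) = (s·x)·I + Σ_k x_k W_k ,

with a tilt vector s (gradient of the average energy) and traceless
symmetric coupling matrices W_k. At the origin all n states are degenerate
by construction; the span of {W_k} in the traceless symmetric space sets
the branching dimension of the intersection (two for a two-state crossing,
up to five for a three-state one).

These models serve as the desk-scale ground truth for the ω-CP machinery:
their adiabatic energies, average-energy field, splitting-polynomial
coefficient c_{n−2} and its Hessian are all available in closed form, and
Latin hypercube sampling around the intersection emulates the way training
geometries are drawn around minimum-energy crossing points in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import qmc

from .cp import PotentialSample

__all__ = [
    "LinearVibronicModel",
    "SampledDataset",
    "first_order_two_state",
    "random_linear_vibronic",
    "traceless_symmetric_basis",
    "latin_hypercube",
    "make_dataset",
]


@dataclass(frozen=True)
class LinearVibronicModel:
    """n-state linear vibronic model ``V(x) = (tilt·x)·I + Σ_k x_k W_k``.

    ``couplings`` has shape (dim, n, n); every W_k must be symmetric and
    traceless so that the origin is an exact n-fold degeneracy and
    ``tilt·x`` is exactly the average-energy field ω(x).
    """

    n_states: int
    dim: int
    tilt: np.ndarray
    couplings: np.ndarray

    def __post_init__(self) -> None:
        if self.n_states < 2 or self.dim < 1:
            raise ValueError("need n_states ≥ 2 and dim ≥ 1")
        tilt = np.asarray(self.tilt, dtype=float)
        w = np.asarray(self.couplings, dtype=float)
        if tilt.shape != (self.dim,):
            raise ValueError(f"tilt must have shape ({self.dim},)")
        if w.shape != (self.dim, self.n_states, self.n_states):
            raise ValueError("couplings must have shape (dim, n, n)")
        for k in range(self.dim):
            if not np.allclose(w[k], w[k].T, atol=1e-12):
                raise ValueError(f"coupling matrix W_{k} is not symmetric")
            if abs(np.trace(w[k])) > 1e-12 * max(1.0, np.abs(w[k]).max()):
                raise ValueError(f"coupling matrix W_{k} is not traceless")
        object.__setattr__(self, "tilt", tilt)
        object.__setattr__(self, "couplings", w)

    # -- closed-form fields ------------------------------------------------

    def potential_matrix(self, coords: np.ndarray) -> np.ndarray:
        coords = self._check_coords(coords)
        return float(self.tilt @ coords) * np.eye(self.n_states) + np.tensordot(
            coords, self.couplings, axes=(0, 0)
        )

    def energies(self, coords: np.ndarray) -> np.ndarray:
        """Sorted adiabatic energies at one point."""
        return np.linalg.eigvalsh(self.potential_matrix(coords))

    def evaluate(self, coords: np.ndarray) -> PotentialSample:
        coords = self._check_coords(coords)
        return PotentialSample(coords=coords, energies=self.energies(coords))

    def omega(self, coords: np.ndarray) -> float:
        """Average adiabatic energy; exactly the linear tilt field."""
        return float(self.tilt @ self._check_coords(coords))

    def cnm2(self, coords: np.ndarray) -> float:
        """Closed-form c_{n−2} field, ``−Tr(M(x)²)/2`` with M = Σ x_k W_k.

        Follows from c_{n−2} = −(1/2n) Σ_{i<j} ΔE_ij² and
        Σ_{i<j} (λ_i−λ_j)² = n·Tr(M²) for a traceless M. The field is an
        exact quadratic form in the coordinates.
        """
        coords = self._check_coords(coords)
        m = np.tensordot(coords, self.couplings, axes=(0, 0))
        return -0.5 * float(np.sum(m * m))

    def cnm2_hessian(self) -> np.ndarray:
        """Analytic Hessian of the c_{n−2} field: ``H_kl = −Tr(W_k W_l)``.

        Its rank equals the branching dimension; its null space spans the
        seam directions.
        """
        w = self.couplings.reshape(self.dim, -1)
        return -(w @ w.T)

    @property
    def branching_rank(self) -> int:
        return int(np.linalg.matrix_rank(self.cnm2_hessian(), tol=1e-10))

    def _check_coords(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float).ravel()
        if coords.size != self.dim:
            raise ValueError(f"expected {self.dim} coordinates, got {coords.size}")
        return coords


@dataclass
class SampledDataset:
    """A list of (geometry, energies) samples plus generation provenance."""

    samples: list[PotentialSample]
    provenance: dict = field(default_factory=dict)
    elements: list[str] | None = None  # species labels for molecular data

    def __post_init__(self) -> None:
        if self.samples:
            d = self.samples[0].dim
            n = self.samples[0].n_states
            for s in self.samples:
                if s.dim != d or s.n_states != n:
                    raise ValueError("all samples must share coordinate and state counts")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def n_states(self) -> int:
        return self.samples[0].n_states if self.samples else 0

    @property
    def dim(self) -> int:
        return self.samples[0].dim if self.samples else 0

    def coords_matrix(self) -> np.ndarray:
        return np.array([s.coords for s in self.samples]).reshape(len(self), -1)

    def energies_matrix(self) -> np.ndarray:
        return np.array([s.energies for s in self.samples]).reshape(len(self), -1)


def first_order_two_state(
    g_norm: float, h_norm: float, s_x: float = 0.0, s_y: float = 0.0
) -> LinearVibronicModel:
    """First-order model of a two-state conical intersection.

    ``V(x, y) = (s_x·x + s_y·y)·I + [[g̃x, h̃y], [h̃y, −g̃x]]`` with adiabatic
    energies ``(s_x x + s_y y) ± sqrt(g̃²x² + h̃²y²)``: a double cone whose
    pitch along the two branching directions is set by g̃ and h̃ (norms of
    the orthogonalized gradient-difference and derivative-coupling vectors)
    and whose principal-axis tilt is set by (s_x, s_y).
    """
    if g_norm <= 0 or h_norm <= 0:
        raise ValueError("g_norm and h_norm must be positive")
    w = np.array(
        [
            [[g_norm, 0.0], [0.0, -g_norm]],
            [[0.0, h_norm], [h_norm, 0.0]],
        ]
    )
    return LinearVibronicModel(
        n_states=2, dim=2, tilt=np.array([s_x, s_y]), couplings=w
    )


def traceless_symmetric_basis(n: int) -> np.ndarray:
    """Orthonormal basis of the traceless symmetric n×n space, fixed order.

    Off-diagonal pair matrices (E_ij + E_ji)/√2 for i<j in row-major order
    first, then diagonal-difference matrices (E_ii − E_jj)/√2 with j = i+1.
    The deterministic ordering lets a requested branching rank select a
    reproducible subspace.
    """
    basis = []
    for i in range(n):
        for j in range(i + 1, n):
            b = np.zeros((n, n))
            b[i, j] = b[j, i] = 1.0 / np.sqrt(2.0)
            basis.append(b)
    for i in range(n - 1):
        b = np.zeros((n, n))
        b[i, i] = 1.0 / np.sqrt(2.0)
        b[i + 1, i + 1] = -1.0 / np.sqrt(2.0)
        basis.append(b)
    return np.array(basis)


def random_linear_vibronic(
    n_states: int,
    dim: int,
    branching_rank: int,
    seed: int,
    tilt_scale: float = 0.2,
) -> LinearVibronicModel:
    """Random LVC model with a prescribed branching dimension.

    The first ``branching_rank`` coordinates carry independent traceless
    symmetric basis matrices scaled by random coefficients in [0.1, 1.0];
    the remaining coordinates carry zero coupling and are pure seam
    directions. The tilt vector is drawn uniformly in ±``tilt_scale``.
    """
    max_rank = n_states * (n_states + 1) // 2 - 1
    if not (0 <= branching_rank <= min(dim, max_rank)):
        raise ValueError(
            f"branching_rank must be in [0, min(dim, {max_rank})] "
            f"for n_states={n_states}, dim={dim}"
        )
    rng = np.random.default_rng(seed)
    basis = traceless_symmetric_basis(n_states)
    w = np.zeros((dim, n_states, n_states))
    scales = rng.uniform(0.1, 1.0, size=branching_rank)
    for k in range(branching_rank):
        w[k] = scales[k] * basis[k]
    tilt = rng.uniform(-tilt_scale, tilt_scale, size=dim)
    return LinearVibronicModel(n_states=n_states, dim=dim, tilt=tilt, couplings=w)


def latin_hypercube(
    dim: int,
    n_samples: int,
    bounds: Sequence[tuple[float, float]] | tuple[float, float],
    seed: int,
) -> np.ndarray:
    """Latin hypercube sample: one point per equal-width bin in each axis.

    ``bounds`` is either one (lo, hi) pair applied to every coordinate or a
    per-coordinate sequence of pairs. Reproducible for a fixed seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be ≥ 1")
    bounds_arr = np.asarray(bounds, dtype=float)
    if bounds_arr.shape == (2,):
        bounds_arr = np.tile(bounds_arr, (dim, 1))
    if bounds_arr.shape != (dim, 2):
        raise ValueError(f"bounds must be (lo, hi) or {dim} pairs")
    lo, hi = bounds_arr[:, 0], bounds_arr[:, 1]
    if np.any(hi <= lo):
        raise ValueError("each bound interval must have hi > lo")
    sampler = qmc.LatinHypercube(d=dim, seed=seed)
    unit = sampler.random(n=n_samples)
    return qmc.scale(unit, lo, hi)


def make_dataset(
    model: LinearVibronicModel,
    coords: np.ndarray,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    provenance: dict | None = None,
) -> SampledDataset:
    """Evaluate the model on every coordinate row; optional Gaussian noise.

    Noise is off by default: the method is designed for noiseless quantum
    chemistry energies. When enabled, i.i.d. N(0, σ²) is added to each
    energy and the energies re-sorted.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.size and coords.shape[1] != model.dim:
        raise ValueError(f"coordinate rows must have length {model.dim}")
    rng = np.random.default_rng(seed)
    samples = []
    for row in coords:
        e = model.energies(row)
        if noise_sigma > 0:
            e = np.sort(e + rng.normal(0.0, noise_sigma, size=e.shape))
        samples.append(PotentialSample(coords=row, energies=e))
    prov = {
        "generator": "linear_vibronic",
        "n_states": model.n_states,
        "dim": model.dim,
        "noise_sigma": noise_sigma,
        "seed": seed,
    }
    if provenance:
        prov.update(provenance)
    return SampledDataset(samples=samples, provenance=prov)
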