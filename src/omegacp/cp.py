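"""Average-energy / characteristic-polynomial (ω-CP) algebra.

A set of ``n`` adiabatic potential energy surfaces ``E_1(R) ≤ ... ≤ E_n(R)``
is non-differentiable (C⁰) across a seam of conical intersection, which
frustrates direct regression of the surfaces. The potential matrix can
instead be decomposed into an average energy and a traceless diagonal
splitting matrix,

    V(R) = ω(R)·I + Z(R),   ω = Tr V / n,   Z_ii = E_i − ω,

and the splitting part represented by the coefficients of the
characteristic polynomial of Z,

    det(λI − Z) = λⁿ + c_{n−1} λ^{n−1} + ... + c_1 λ + c_0 ,

with c_{n−1} ≡ 0 because Z is traceless. Both ω and the coefficients
c_0..c_{n−2} are smooth functions of the nuclear coordinates even across
intersection seams, and they are invariant to the choice of electronic
basis (the characteristic polynomial is a similarity invariant). The
adiabatic energies are recovered as ω plus the eigenvalues of the
companion matrix of the polynomial.

This module is pure, deterministic algebra: energies → (ω, coefficients),
back again, and the identities used as test oracles elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import companion

__all__ = [
    "PotentialSample",
    "CPRecord",
    "energies_to_cp",
    "cp_to_energies",
    "cp_to_energies_projected",
    "gap_sum_identity",
    "cp_invariance_check",
]

#: internal tolerance on the (dropped) c_{n−1} coefficient, relative to max(1, ‖E‖)
_TRACELESS_RTOL = 1e-12

#: eigenvalues of the companion matrix with |imag| above this (relative) are an error
_IMAG_RTOL = 1e-8


@dataclass(frozen=True)
class PotentialSample:
    """One nuclear geometry with its sorted adiabatic energies.

    ``coords`` is the flattened coordinate vector (Å for Cartesian molecular
    geometries, dimensionless for abstract model coordinates); ``energies``
    are the ``n ≥ 2`` adiabatic energies in Hartree, ascending.
    """

    coords: np.ndarray
    energies: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        energies = np.asarray(self.energies, dtype=float)
        if coords.ndim != 1 or coords.size < 1:
            raise ValueError("coords must be a 1-D vector with at least one entry")
        if energies.ndim != 1 or energies.size < 2:
            raise ValueError("at least two adiabatic energies are required")
        if not np.all(np.isfinite(coords)) or not np.all(np.isfinite(energies)):
            raise ValueError("coords and energies must be finite")
        if np.any(np.diff(energies) < 0):
            raise ValueError("energies must be sorted ascending")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "energies", energies)

    @property
    def n_states(self) -> int:
        return self.energies.size

    @property
    def dim(self) -> int:
        return self.coords.size


@dataclass(frozen=True)
class CPRecord:
    """ω plus the characteristic-polynomial coefficients of the splitting matrix.

    ``coeffs`` stores ``(c_0, ..., c_{n−2})`` in ascending power order;
    ``c_i`` carries units of Hartree^(n−i). The implicit ``c_{n−1}`` is zero
    by tracelessness of Z and is never stored.
    """

    omega: float
    coeffs: np.ndarray
    n_states: int = field(default=0)

    def __post_init__(self) -> None:
        coeffs = np.atleast_1d(np.asarray(self.coeffs, dtype=float))
        n = self.n_states if self.n_states else coeffs.size + 1
        if n < 2 or coeffs.size != n - 1:
            raise ValueError(
                f"need n−1 coefficients (c_0..c_{{n−2}}) for n={n} states, got {coeffs.size}"
            )
        if not np.isfinite(self.omega) or not np.all(np.isfinite(coeffs)):
            raise ValueError("omega and coefficients must be finite")
        object.__setattr__(self, "coeffs", coeffs)
        object.__setattr__(self, "n_states", n)


def energies_to_cp(energies: np.ndarray) -> CPRecord:
    """Map sorted adiabatic energies to their (ω, CP-coefficient) representation.

    The splitting eigenvalues are ``z_i = E_i − ω`` and the polynomial
    ``Π_i (λ − z_i)`` is expanded by iterative convolution. The internally
    computed ``c_{n−1}`` (= −Σ z_i) must vanish to within rounding, is
    checked, and dropped.
    """
    energies = np.asarray(energies, dtype=float)
    if energies.ndim != 1 or energies.size < 2:
        raise ValueError("need a 1-D vector of at least two energies")
    if not np.all(np.isfinite(energies)):
        raise ValueError("energies must be finite")
    omega = float(np.mean(energies))
    z = energies - omega
    # np.poly expands Π(λ − z_i) by iterative convolution, descending powers
    poly = np.poly(z)  # [1, c_{n-1}, ..., c_1, c_0]
    scale = max(1.0, float(np.linalg.norm(energies)))
    c_nm1 = poly[1]
    if abs(c_nm1) > _TRACELESS_RTOL * scale * energies.size:
        raise ArithmeticError(
            f"traceless check failed: c_(n-1) = {c_nm1:.3e} should vanish"
        )
    coeffs = poly[2:][::-1].copy()  # (c_0, ..., c_{n-2}) ascending
    return CPRecord(omega=omega, coeffs=coeffs, n_states=energies.size)


def _companion_poly(record: CPRecord) -> np.ndarray:
    """Monic polynomial [1, 0, c_{n−2}, ..., c_0] in descending powers."""
    n = record.n_states
    poly = np.zeros(n + 1)
    poly[0] = 1.0
    poly[2:] = record.coeffs[::-1]
    return poly


def cp_to_energies(record: CPRecord) -> np.ndarray:
    """Recover the sorted adiabatic energies from a :class:`CPRecord`.

    Builds the companion matrix of ``λⁿ + 0·λ^{n−1} + c_{n−2}λ^{n−2} + ... + c_0``
    and takes its eigenvalues. For coefficients generated from a real
    spectrum the roots are real; a root with a non-negligible imaginary part
    signals a coefficient combination not realizable by any real symmetric
    splitting matrix and raises :class:`ArithmeticError`.
    """
    roots = _cp_roots(record, on_complex="raise")
    return np.sort(roots) + record.omega


def _cp_roots(record: CPRecord, on_complex: str = "raise") -> np.ndarray:
    """Companion-matrix roots of the splitting polynomial.

    ``on_complex`` is ``"raise"`` or ``"project"`` (take real parts); the
    projecting variant backs the surrogate prediction path, where regression
    error can push coefficients off the realizable manifold.
    """
    poly = _companion_poly(record)
    roots = np.linalg.eigvals(companion(poly))
    bad = np.abs(roots.imag) > _IMAG_RTOL * np.maximum(1.0, np.abs(roots.real))
    if np.any(bad):
        if on_complex == "raise":
            raise ArithmeticError(
                "companion matrix has complex eigenvalues "
                f"(max |imag| = {np.abs(roots.imag).max():.3e}); the CP record is "
                "not realizable by a real spectrum"
            )
    return roots.real


def cp_to_energies_projected(record: CPRecord) -> tuple[np.ndarray, bool]:
    """Reconstruction tolerant of off-manifold coefficients.

    Regression error can produce coefficient combinations whose splitting
    polynomial has complex roots (no real spectrum realizes them). Instead
    of failing, the real parts are kept and a flag returned so downstream
    consumers can mark the point. Exact records behave as
    :func:`cp_to_energies`.
    """
    poly = _companion_poly(record)
    roots = np.linalg.eigvals(companion(poly))
    was_complex = bool(
        np.any(np.abs(roots.imag) > _IMAG_RTOL * np.maximum(1.0, np.abs(roots.real)))
    )
    return np.sort(roots.real) + record.omega, was_complex


def gap_sum_identity(energies: np.ndarray) -> float:
    """Return ``−(1/2n) Σ_{i<j} (E_i − E_j)²``, which equals ``c_{n−2}``.

    The coefficient ``c_{n−2}`` of the splitting polynomial is a negative
    sum of squared adiabatic gaps: it vanishes exactly at an ``n``-fold
    degeneracy and is lifted quadratically along branching directions,
    which is why its Hessian at an intersection spans the branching space.
    """
    energies = np.asarray(energies, dtype=float)
    if energies.ndim != 1 or energies.size < 2:
        raise ValueError("need a 1-D vector of at least two energies")
    n = energies.size
    diffs = energies[:, None] - energies[None, :]
    return float(-np.sum(np.triu(diffs, 1) ** 2) / (2 * n))


def cp_invariance_check(
    matrix: np.ndarray, transform: np.ndarray, rtol: float = 1e-10
) -> bool:
    """Check CP-coefficient invariance under an orthogonal similarity transform.

    The characteristic polynomial of the traceless part of a symmetric
    matrix is unchanged by ``M → QᵀMQ`` for orthogonal ``Q`` — the algebraic
    fact that makes the ω-CP representation independent of the electronic
    basis (adiabatic or diabatic). Used as a property-test oracle.
    """
    matrix = np.asarray(matrix, dtype=float)
    transform = np.asarray(transform, dtype=float)
    n = matrix.shape[0]
    if matrix.shape != (n, n) or transform.shape != (n, n):
        raise ValueError("matrix and transform must be square and same-shaped")
    if not np.allclose(matrix, matrix.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    if not np.allclose(transform.T @ transform, np.eye(n), atol=1e-10):
        raise ValueError("transform is not orthogonal to 1e-10")

    def traceless_cp(m: np.ndarray) -> np.ndarray:
        z = m - np.trace(m) / n * np.eye(n)
        return np.poly(np.linalg.eigvalsh(z))

    a = traceless_cp(matrix)
    b = traceless_cp(transform.T @ matrix @ transform)
    scale = np.maximum(np.abs(a), 1e-300)
    return bool(np.all(np.abs(a - b) <= rtol * np.maximum(1.0, scale)))
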