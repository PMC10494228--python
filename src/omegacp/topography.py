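"""Branching/seam-space analysis and cone topography at conical intersections.

At an intersection point the coefficient c_{n−2} of the splitting
polynomial — a negative sum of squared adiabatic gaps — has a maximum of
zero. Its Hessian there has a column space spanning the branching
directions (degeneracy lifted at first order, quadratic in c_{n−2}) and a
null space spanning the seam (degeneracy preserved, quartic in c_{n−2}).
For a two-state crossing the two nonzero eigenvalues are −2g̃² and −2h̃²
where g̃ and h̃ are the norms of the orthogonalized gradient-difference
and derivative-coupling vectors, and the tilt parameters are projections
of the average-energy gradient onto the branching unit vectors:
s_x = ∇ω·x̂, s_y = ∇ω·ŷ.

All quantities here are computed from two scalar fields only, ω(R) and
c_{n−2}(R), which may come from an analytic vibronic model or from fitted
surrogates — the route by which regression models of smooth fields yield
quantitative intersection topography.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.linalg import subspace_angles
from scipy.optimize import minimize

from .cp import gap_sum_identity
from .krr import SurrogateEnsemble, predict_energies
from .models import LinearVibronicModel

__all__ = [
    "ConeReport",
    "BranchingSplit",
    "GapScan",
    "MECIResult",
    "omega_field",
    "cnm2_field",
    "hessian_cnm2",
    "split_branching_seam",
    "cone_parameters",
    "orthogonalize_gh",
    "principal_angles",
    "gap_scan",
    "locate_meci",
]

#: default finite-difference step on analytic fields (coordinate units)
DEFAULT_STEP_ANALYTIC = 1e-3
#: default step on fitted surrogates: large enough that second differences
#: do not amplify interpolation residuals, small enough for O(step²) truncation
DEFAULT_STEP_SURROGATE = 0.02
#: eigenvalues below this fraction of max |λ| count as seam (zero) directions
DEFAULT_RELATIVE_THRESHOLD = 1e-2
#: branching eigenvalues closer than this (relative) are treated as degenerate
DEGENERACY_RTOL = 1e-2

FieldFn = Callable[[np.ndarray], np.ndarray]


def omega_field(obj: LinearVibronicModel | SurrogateEnsemble) -> FieldFn:
    """Vectorized average-energy field ω(R) of a model or surrogate."""
    if isinstance(obj, LinearVibronicModel):
        return lambda pts: np.atleast_2d(pts) @ obj.tilt
    if isinstance(obj, SurrogateEnsemble):
        if obj.mode == "omega_cp":
            return lambda pts: obj.predict_fields(pts)["omega"]
        return lambda pts: predict_energies(obj, pts).energies.mean(axis=1)
    raise TypeError(f"no ω field for {type(obj).__name__}")


def cnm2_field(obj: LinearVibronicModel | SurrogateEnsemble) -> FieldFn:
    """Vectorized c_{n−2}(R) field of a model or surrogate.

    For a direct-energy surrogate the field is assembled from the predicted
    energies through the squared-gap identity — the route by which the
    branching-space diagnostic is applied to a model that never learned
    the coefficient itself.
    """
    if isinstance(obj, LinearVibronicModel):
        return lambda pts: np.array([obj.cnm2(p) for p in np.atleast_2d(pts)])
    if isinstance(obj, SurrogateEnsemble):
        label = f"c_{obj.n_states - 2}"
        if obj.mode == "omega_cp":
            return lambda pts: obj.predict_fields(pts)[label]
        return lambda pts: np.array(
            [gap_sum_identity(e) for e in predict_energies(obj, pts).energies]
        )
    raise TypeError(f"no c_(n-2) field for {type(obj).__name__}")


def default_step(obj) -> float:
    return (
        DEFAULT_STEP_SURROGATE
        if isinstance(obj, SurrogateEnsemble)
        else DEFAULT_STEP_ANALYTIC
    )


def hessian_cnm2(field: FieldFn, point: np.ndarray, step: float) -> np.ndarray:
    """Central-difference Hessian of a scalar field, explicitly symmetrized.

    ``field`` maps an (m, d) matrix of points to m values; all stencil
    points are evaluated in one batch. O(step²) accurate; exact (up to
    rounding) on quadratics.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    point = np.asarray(point, dtype=float).ravel()
    d = point.size
    eye = np.eye(d)
    pts = [point]
    for i in range(d):
        pts += [point + step * eye[i], point - step * eye[i]]
    pairs = [(i, j) for i in range(d) for j in range(i + 1, d)]
    for i, j in pairs:
        ei, ej = step * eye[i], step * eye[j]
        pts += [point + ei + ej, point + ei - ej, point - ei + ej, point - ei - ej]
    vals = np.asarray(field(np.array(pts)), dtype=float)
    f0 = vals[0]
    h = np.empty((d, d))
    for i in range(d):
        fp, fm = vals[1 + 2 * i], vals[2 + 2 * i]
        h[i, i] = (fp - 2.0 * f0 + fm) / step**2
    off = vals[1 + 2 * d :]
    for k, (i, j) in enumerate(pairs):
        fpp, fpm, fmp, fmm = off[4 * k : 4 * k + 4]
        h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * step**2)
    return 0.5 * (h + h.T)


def _gradient(field: FieldFn, point: np.ndarray, step: float) -> np.ndarray:
    point = np.asarray(point, dtype=float).ravel()
    d = point.size
    eye = np.eye(d)
    pts = np.concatenate([point + step * eye, point - step * eye])
    vals = np.asarray(field(pts), dtype=float)
    return (vals[:d] - vals[d:]) / (2.0 * step)


@dataclass(frozen=True)
class BranchingSplit:
    """Eigendecomposition of the c_{n−2} Hessian, split at a threshold."""

    eigenvalues: np.ndarray  # all, descending |λ|
    branching_values: np.ndarray
    branching_vectors: np.ndarray  # columns, orthonormal
    seam_values: np.ndarray
    seam_vectors: np.ndarray  # columns, orthonormal complement

    @property
    def branching_dim(self) -> int:
        return self.branching_values.size


def split_branching_seam(
    hessian: np.ndarray, relative_threshold: float = DEFAULT_RELATIVE_THRESHOLD
) -> BranchingSplit:
    """Partition Hessian eigenpairs into branching (column) and seam (null) spaces.

    Eigenvalues with |λ| ≥ threshold·max|λ| are branching; ordering is by
    descending magnitude, and each eigenvector's first nonzero component is
    made positive so reports are deterministic. A zero Hessian yields
    branching dimension 0 (no intersection curvature at the point).
    """
    hessian = np.asarray(hessian, dtype=float)
    if not np.allclose(hessian, hessian.T, atol=1e-10):
        raise ValueError("hessian must be symmetric")
    vals, vecs = np.linalg.eigh(hessian)
    order = np.argsort(-np.abs(vals), kind="stable")
    vals, vecs = vals[order], vecs[:, order]
    # deterministic orientation: largest-magnitude component positive (robust
    # to noise in near-zero leading components, unlike first-nonzero-positive)
    for k in range(vecs.shape[1]):
        if vecs[np.argmax(np.abs(vecs[:, k])), k] < 0:
            vecs[:, k] *= -1.0
    max_mag = np.abs(vals).max() if vals.size else 0.0
    if max_mag == 0.0:
        mask = np.zeros(vals.size, dtype=bool)
    else:
        mask = np.abs(vals) >= relative_threshold * max_mag
    return BranchingSplit(
        eigenvalues=vals,
        branching_values=vals[mask],
        branching_vectors=vecs[:, mask],
        seam_values=vals[~mask],
        seam_vectors=vecs[:, ~mask],
    )


def _axis_aligned_basis(vectors: np.ndarray) -> np.ndarray:
    """Orthonormal basis of span(vectors) closest to the coordinate axes.

    Projects the coordinate axes onto the subspace in axis order and
    Gram–Schmidt-orthonormalizes the projections. Any orthonormal basis of
    a degenerate eigenvalue block is an eigenbasis, so this is a pure,
    deterministic convention; for models whose couplings live on the
    leading coordinate axes it coincides with the analytic eigenvectors.
    """
    d, k = vectors.shape
    proj = vectors @ vectors.T
    basis: list[np.ndarray] = []
    for i in range(d):
        v = proj[:, i].copy()
        for b in basis:
            v -= (b @ v) * b
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            basis.append(v / norm)
        if len(basis) == k:
            break
    out = np.column_stack(basis)
    for j in range(k):
        if out[np.argmax(np.abs(out[:, j])), j] < 0:
            out[:, j] *= -1.0
    return out


@dataclass(frozen=True)
class ConeReport:
    """Topography of a two-state conical intersection at one point.

    g_norm ≥ h_norm set the pitch of the cone along the branching unit
    vectors x (steeper) and y; s_x, s_y tilt its principal axis. Units are
    E_h per coordinate unit (E_h/Å for Cartesian geometries).
    """

    point: np.ndarray
    hessian: np.ndarray
    eigenvalues: np.ndarray
    branching_vectors: np.ndarray
    seam_vectors: np.ndarray
    branching_dim: int
    g_norm: float
    h_norm: float
    s_x: float
    s_y: float
    principal_angles_deg: np.ndarray | None = None

    def as_dict(self) -> dict:
        out = {
            "point": self.point.tolist(),
            "branching_dim": self.branching_dim,
            "hessian_eigenvalues": self.eigenvalues.tolist(),
            "g_norm": self.g_norm,
            "h_norm": self.h_norm,
            "s_x": self.s_x,
            "s_y": self.s_y,
        }
        if self.principal_angles_deg is not None:
            out["principal_angles_deg"] = self.principal_angles_deg.tolist()
        return out

    def table(self) -> str:
        """Human-readable one-line parameter table."""
        cols = ["g~", "h~", "s_x", "s_y"]
        vals = [self.g_norm, self.h_norm, self.s_x, self.s_y]
        if self.principal_angles_deg is not None and self.principal_angles_deg.size >= 2:
            cols = ["theta_x", "theta_y"] + cols
            vals = list(self.principal_angles_deg[:2]) + vals
        head = "  ".join(f"{c:>8s}" for c in cols)
        body = "  ".join(f"{v:8.4f}" for v in vals)
        return head + "\n" + body


def cone_parameters(
    obj: LinearVibronicModel | SurrogateEnsemble,
    ci_point: np.ndarray,
    step: float | None = None,
    relative_threshold: float = DEFAULT_RELATIVE_THRESHOLD,
    reference_branching: np.ndarray | None = None,
) -> ConeReport:
    """Extract (g̃, h̃, s_x, s_y) and branching vectors at a two-state CI point.

    The two retained Hessian eigenvalues λ₁, λ₂ (descending magnitude,
    both required negative) give g̃ = √(−λ₁/2) and h̃ = √(−λ₂/2); the tilt
    parameters are the central-difference gradient of ω projected on the
    corresponding eigenvectors. If ``reference_branching`` (a d×k
    orthonormal set) is given, principal angles between the recovered and
    reference branching spaces are reported — a subspace-level comparison
    immune to the eigenvector ambiguity of symmetric cones (g̃ = h̃).
    """
    ci_point = np.asarray(ci_point, dtype=float).ravel()
    if step is None:
        step = default_step(obj)
    hess = hessian_cnm2(cnm2_field(obj), ci_point, step)
    split = split_branching_seam(hess, relative_threshold)
    if split.branching_dim != 2:
        raise ValueError(
            f"unsupported topology: branching dimension {split.branching_dim}, "
            "cone parameters are defined for two-state intersections "
            "(branching dimension 2) only"
        )
    lam = split.branching_values
    scale = np.abs(lam).max()
    if np.any(lam > 1e-6 * scale):
        raise ArithmeticError(
            f"inconsistent intersection: positive branching curvature {lam} "
            "(c_(n-2) must have a local maximum of 0 at a CI)"
        )
    g_norm = float(np.sqrt(max(-lam[0], 0.0) / 2.0))
    h_norm = float(np.sqrt(max(-lam[1], 0.0) / 2.0))
    branching_vectors = split.branching_vectors
    if abs(lam[0] - lam[1]) <= DEGENERACY_RTOL * abs(lam[0]):
        # symmetric cone (g̃ ≈ h̃): individual eigenvectors are arbitrary up
        # to an in-plane rotation and, on fitted surfaces, noise-dominated.
        # Canonicalize to the eigenbasis closest to the coordinate axes.
        branching_vectors = _axis_aligned_basis(branching_vectors)
    x_vec = branching_vectors[:, 0]
    y_vec = branching_vectors[:, 1]
    grad_omega = _gradient(omega_field(obj), ci_point, step)
    s_x = float(grad_omega @ x_vec)
    s_y = float(grad_omega @ y_vec)
    angles = None
    if reference_branching is not None:
        angles = principal_angles(branching_vectors, reference_branching)
    return ConeReport(
        point=ci_point,
        hessian=hess,
        eigenvalues=split.eigenvalues,
        branching_vectors=branching_vectors,
        seam_vectors=split.seam_vectors,
        branching_dim=split.branching_dim,
        g_norm=g_norm,
        h_norm=h_norm,
        s_x=s_x,
        s_y=s_y,
        principal_angles_deg=angles,
    )


def orthogonalize_gh(
    g: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Rotate a (gradient-difference, derivative-coupling) pair to orthogonality.

    The pair is mixed by the angle β with tan(2β) = 2(g·h)/(g·g − h·h),
    after which the rotated vectors are mutually orthogonal; returns unit
    vectors and norms, larger norm first. Parallel inputs give one
    (near-)zero norm — the degenerate limit.
    """
    g = np.asarray(g, dtype=float).ravel()
    h = np.asarray(h, dtype=float).ravel()
    if g.size != h.size:
        raise ValueError("g and h must have the same length")
    if np.linalg.norm(g) == 0.0 and np.linalg.norm(h) == 0.0:
        raise ValueError("g and h cannot both be zero")
    beta = 0.5 * np.arctan2(2.0 * (g @ h), (g @ g) - (h @ h))
    gr = np.cos(beta) * g + np.sin(beta) * h
    hr = -np.sin(beta) * g + np.cos(beta) * h
    ng, nh = np.linalg.norm(gr), np.linalg.norm(hr)
    if nh > ng:
        gr, hr, ng, nh = hr, gr, nh, ng
    x = gr / ng if ng > 0 else gr
    y = hr / nh if nh > 0 else hr
    return x, y, float(ng), float(nh)


def principal_angles(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Principal angles (degrees, ascending) between two subspaces.

    Columns of ``a`` and ``b`` are orthonormal spanning sets in the same
    ambient dimension. The comparison is at the subspace level: an in-plane
    rotation of one spanning set (e.g. the arbitrary eigenvectors of a
    symmetric cone) leaves the angles at zero.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[0] != b.shape[0]:
        raise ValueError("subspaces must share the ambient dimension")
    ang = subspace_angles(a, b)
    return np.degrees(np.sort(ang))


@dataclass(frozen=True)
class GapScan:
    """Energies and adjacent gaps along a scan path."""

    points: np.ndarray
    energies: np.ndarray
    gaps: np.ndarray
    min_gap: float
    min_gap_point: np.ndarray


def _energies_at(obj, points: np.ndarray) -> np.ndarray:
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if isinstance(obj, LinearVibronicModel):
        return np.array([obj.energies(p) for p in points])
    if isinstance(obj, SurrogateEnsemble):
        return predict_energies(obj, points).energies
    raise TypeError(f"cannot evaluate energies of {type(obj).__name__}")


def gap_scan(obj, points: np.ndarray) -> GapScan:
    """Evaluate energies along a line or grid; report the minimum adjacent gap.

    The avoided-crossing diagnostic: scanned through a true intersection, a
    direct-energy surrogate shows a strictly positive minimum gap while an
    ω-CP surrogate closes it.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    energies = _energies_at(obj, points)
    gaps = np.diff(energies, axis=1)
    lowest = gaps.min(axis=1)
    k = int(np.argmin(lowest))
    return GapScan(
        points=points,
        energies=energies,
        gaps=gaps,
        min_gap=float(lowest[k]),
        min_gap_point=points[k],
    )


@dataclass(frozen=True)
class MECIResult:
    point: np.ndarray
    gap: float
    lower_energy: float
    converged: bool


def locate_meci(
    obj,
    start: np.ndarray,
    penalty_weights: tuple[float, ...] = (1e2, 1e3, 1e4, 1e5),
    gap_tol: float = 1e-4,
    search_radius: float = 1.0,
) -> MECIResult:
    """Penalty-function search for a minimum-energy two-state crossing point.

    Minimizes ``E_lower + σ·gap²`` with an increasing penalty schedule σ
    using derivative-free local search (Nelder–Mead), warm-starting each
    stage from the last. Useful on surrogates when analytic gradients of
    the underlying electronic-structure method are unavailable. The search
    is confined to ``search_radius`` around the start point: on first-order
    models the seam energy is unbounded below, and on surrogates predictions
    far outside the training region are meaningless. Returns the best point
    with a convergence flag (gap ≤ ``gap_tol``).
    """
    start = np.asarray(start, dtype=float).ravel()
    n_states = obj.n_states
    if n_states != 2:
        raise ValueError("MECI search is implemented for two-state models only")

    def objective(sigma):
        def f(p):
            overshoot = np.linalg.norm(p - start) - search_radius
            if overshoot > 0:
                return 1e3 * (1.0 + overshoot)
            e = _energies_at(obj, p[None, :])[0]
            return e[0] + sigma * (e[1] - e[0]) ** 2

        return f

    point = start
    for sigma in penalty_weights:
        res = minimize(
            objective(sigma),
            point,
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000},
        )
        point = res.x
        e = _energies_at(obj, point[None, :])[0]
        if e[1] - e[0] <= gap_tol:
            break
    e = _energies_at(obj, point[None, :])[0]
    gap = float(e[1] - e[0])
    return MECIResult(
        point=point, gap=gap, lower_energy=float(e[0]), converged=gap <= gap_tol
    )
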