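"""Geometry featurization: raw model coordinates or an invariant power spectrum.

Abstract model coordinates already live in a well-defined vector space and
are passed through unchanged (``raw`` mode). Molecular Cartesian geometries
are not directly usable as regression inputs — the physics is invariant to
rigid rotations, translations and permutations of like atoms — so ``soap``
mode maps them to a rotation/translation-invariant power spectrum of a
smeared atomic neighbor density, in the spirit of the smooth-overlap
(SOAP) family of atomic-environment descriptors.

The implementation here is a deliberately reduced power spectrum: around
each atomic center the neighbor density of each species is expanded in
``n_max`` Gaussian radial bumps times real spherical harmonics up to
``l_max``, with a smooth cosine cutoff at ``r_cut``, and the expansion
coefficients are contracted over the magnetic index m,

    p_{(s n),(s' n')}^{l} = Σ_m c_{snlm} c_{s'n'lm} ,

which is exactly rotation invariant. Averaging the per-center spectra over
all centers additionally yields permutation invariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import sph_harm_y

__all__ = ["DescriptorConfig", "featurize", "feature_length"]


@dataclass(frozen=True)
class DescriptorConfig:
    """Featurization settings.

    mode
        ``"raw"`` (identity on model coordinates) or ``"soap"``.
    r_cut
        Neighbor cutoff radius, Å.
    n_max, l_max
        Radial basis size and angular momentum cutoff of the expansion.
    sigma_atom
        Width (Å) of the Gaussian radial bumps (density smearing scale).
    species
        Ordered element symbols expected in the molecules.
    reduction
        ``"average"`` over centers (permutation invariant, size-independent
        feature length) or ``"concatenate"`` by center.
    """

    mode: str = "raw"
    r_cut: float = 5.0
    n_max: int = 6
    l_max: int = 4
    sigma_atom: float = 0.5
    species: tuple[str, ...] = field(default_factory=tuple)
    reduction: str = "average"

    def __post_init__(self) -> None:
        if self.mode not in ("raw", "soap"):
            raise ValueError(f"unknown descriptor mode {self.mode!r}")
        if self.reduction not in ("average", "concatenate"):
            raise ValueError(f"unknown reduction {self.reduction!r}")
        if self.mode == "soap":
            if self.r_cut <= 0 or self.sigma_atom <= 0:
                raise ValueError("soap mode requires r_cut > 0 and sigma_atom > 0")
            if self.n_max < 1 or self.l_max < 0:
                raise ValueError("soap mode requires n_max ≥ 1 and l_max ≥ 0")
            if not self.species:
                raise ValueError("soap mode requires a nonempty species list")
        object.__setattr__(self, "species", tuple(self.species))


def feature_length(config: DescriptorConfig, d: int, n_atoms: int | None = None) -> int:
    """Closed-form output length of :func:`featurize` for input dimension d."""
    if config.mode == "raw":
        return d
    a = len(config.species) * config.n_max
    per_center = a * (a + 1) // 2 * (config.l_max + 1)
    if config.reduction == "average":
        return per_center
    if n_atoms is None:
        n_atoms = d // 3
    return n_atoms * per_center


def _real_sph_harm(l_max: int, unit_vecs: np.ndarray) -> np.ndarray:
    """Real spherical harmonics Y_lm for all l ≤ l_max on unit vectors.

    Returns shape (n_points, (l_max+1)²), index l² + l + m.
    """
    x, y, z = unit_vecs[:, 0], unit_vecs[:, 1], unit_vecs[:, 2]
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    phi = np.arctan2(y, x)
    out = np.empty((unit_vecs.shape[0], (l_max + 1) ** 2))
    for l in range(l_max + 1):
        for m in range(0, l + 1):
            ylm = sph_harm_y(l, m, theta, phi)
            idx = l * l + l
            if m == 0:
                out[:, idx] = ylm.real
            else:
                # Condon–Shortley-consistent real combinations
                out[:, idx + m] = np.sqrt(2.0) * (-1.0) ** m * ylm.real
                out[:, idx - m] = np.sqrt(2.0) * (-1.0) ** m * ylm.imag
    return out


def _radial_basis(config: DescriptorConfig, r: np.ndarray) -> np.ndarray:
    """Gaussian bumps centered on an equispaced radial grid, with smooth cutoff."""
    centers = np.linspace(0.0, config.r_cut, config.n_max)
    g = np.exp(-((r[:, None] - centers[None, :]) ** 2) / (2.0 * config.sigma_atom**2))
    fcut = 0.5 * (np.cos(np.pi * r / config.r_cut) + 1.0)
    return g * fcut[:, None]


def _power_spectrum_one_center(
    config: DescriptorConfig,
    center: np.ndarray,
    positions: np.ndarray,
    species_idx: np.ndarray,
) -> np.ndarray:
    n_species = len(config.species)
    n_max, l_max = config.n_max, config.l_max
    coeffs = np.zeros((n_species * n_max, (l_max + 1) ** 2))
    disp = positions - center
    r = np.linalg.norm(disp, axis=1)
    mask = (r > 1e-10) & (r < config.r_cut)  # the center itself is excluded
    if np.any(mask):
        disp, r, sp = disp[mask], r[mask], species_idx[mask]
        ylm = _real_sph_harm(l_max, disp / r[:, None])
        gn = _radial_basis(config, r)
        for s in range(n_species):
            sel = sp == s
            if np.any(sel):
                coeffs[s * n_max : (s + 1) * n_max] = gn[sel].T @ ylm[sel]
    # contract over m within each l block; upper triangle over (species, n) pairs
    a = coeffs.shape[0]
    iu, ju = np.triu_indices(a)
    blocks = []
    for l in range(l_max + 1):
        cl = coeffs[:, l * l : (l + 1) ** 2]
        pl = cl @ cl.T
        blocks.append(pl[iu, ju])
    return np.concatenate(blocks)


def featurize(
    config: DescriptorConfig,
    coords: np.ndarray,
    elements: Sequence[str] | None = None,
) -> np.ndarray:
    """Map one flattened geometry to its feature vector.

    Raw mode returns ``coords`` unchanged. Soap mode interprets ``coords``
    as flattened Cartesian positions (length divisible by 3) with matching
    ``elements`` labels and returns the invariant power spectrum.
    """
    coords = np.asarray(coords, dtype=float).ravel()
    if config.mode == "raw":
        return coords.copy()
    if coords.size % 3 != 0:
        raise ValueError("soap mode requires a coordinate length divisible by 3")
    n_atoms = coords.size // 3
    if elements is None or len(elements) != n_atoms:
        raise ValueError(f"soap mode requires {n_atoms} element labels")
    unknown = set(elements) - set(config.species)
    if unknown:
        raise ValueError(f"elements {sorted(unknown)} not in configured species")
    positions = coords.reshape(n_atoms, 3)
    species_idx = np.array([config.species.index(e) for e in elements])
    spectra = np.array(
        [
            _power_spectrum_one_center(config, positions[i], positions, species_idx)
            for i in range(n_atoms)
        ]
    )
    if config.reduction == "average":
        return spectra.mean(axis=0)
    return spectra.ravel()


def featurize_many(
    config: DescriptorConfig,
    coords: np.ndarray,
    elements: Sequence[str] | None = None,
) -> np.ndarray:
    """Featurize each row of a coordinate matrix; returns (n_rows, n_features)."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    return np.array([featurize(config, row, elements) for row in coords])
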