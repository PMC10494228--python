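# Methods

## Model and representation

`omegacp` treats a set of n adiabatic potential energy surfaces as the
eigenvalues of an n×n potential matrix V(R) and works in the decomposition

    V(R) = ω(R)·I + Z(R),    ω = Tr V / n,    Z = diag(E_i − ω).

The learned quantities are ω and the characteristic-polynomial (CP)
coefficients c_0 … c_{n−2} of Z (c_{n−1} vanishes identically because Z is
traceless). These n scalar fields are smooth across conical intersection
(CI) seams — where the E_i themselves are only C⁰ — and are invariant
under any orthogonal change of electronic basis, since both the trace and
the characteristic polynomial are similarity invariants. Energies are
recovered as ω plus the eigenvalues of the companion matrix of
λⁿ + c_{n−2}λ^{n−2} + … + c_0.

The coefficients are computed by convolution expansion of Π_i (λ − z_i)
with z_i = E_i − ω (`numpy.poly`). For a diagonal Z this is exact up to
rounding and avoids the cancellation pitfalls of Newton-identity
recursions at small n. The internally computed c_{n−1} is asserted to
vanish to 1e−12 (relative to max(1, ‖E‖)) and dropped.

Two algebraic facts are load-bearing and are enforced by tests:

* c_{n−2} = −(1/2n) Σ_{i<j} (E_i − E_j)²  — a non-positive sum of squared
  gaps, zero exactly at an n-fold degeneracy;
* the CP coefficients of the traceless part of any symmetric matrix are
  unchanged by orthogonal similarity transforms.

## Branching-space analysis

Each squared gap is lifted quadratically at a CI along branching
directions and quartically along seam directions, so the Hessian of
c_{n−2} at a CI point has a column space equal to the branching space and
a null space equal to the seam space. For a two-state CI the two nonzero
eigenvalues equal −2g̃² and −2h̃² (g̃, h̃ the norms of the orthogonalized
gradient-difference and derivative-coupling vectors) and the cone tilt is
s_x = ∇ω·x̂, s_y = ∇ω·ŷ on the branching eigenvectors. The unscaled
gradient projection is used for the tilt: it reproduces the analytic
two-state model exactly and carries E_h per coordinate-unit (E_h/Å for
Cartesian data), the units in which such parameters are conventionally
reported.

Numerical choices:

* **Hessian/gradients** are central finite differences, explicitly
  symmetrized. Default step: 1e−3 coordinate units on analytic fields;
  0.02 on fitted surrogates. Second differences divide the surrogate's
  interpolation residual (~1e−8) by step², so a 1e−3 step would amplify it
  to ~1e−2 while the larger step keeps truncation error O(step²) ≈ 4e−4
  on the quadratic-dominated c_{n−2} field. Both defaults are overridable.
* **Branching/seam threshold**: eigenvalues below 1e−2 of the largest
  magnitude count as seam. Surrogate Hessians are never exactly zero; on
  noiseless analytic models the split is stable for thresholds across
  [1e−3, 1e−1] whenever the true eigenvalue spread allows it.
* **Eigenvector orientation**: each eigenvector's largest-magnitude
  component is made positive. (A first-nonzero-positive rule was rejected:
  when the leading component is noise-level on a fitted surface its sign
  is random, and the tilt parameters inherit the flip.)
* **Symmetric cones (g̃ ≈ h̃ within 1%)**: the two branching eigenvalues
  are degenerate, so individual eigenvectors are arbitrary up to an
  in-plane rotation and, on surrogates, noise-determined. Any orthonormal
  basis of a degenerate block is an eigenbasis; the implementation
  canonicalizes to the basis closest to the coordinate axes (Gram–Schmidt
  of the projected axes). Subspace comparisons always go through principal
  angles, which are immune to this ambiguity.
* **MECI search** minimizes E_lower + σ·gap² over an increasing penalty
  schedule σ ∈ {1e2 … 1e5} with Nelder–Mead, confined to a search radius
  (default 1.0) around the start: first-order models are unbounded below
  along tilted seams, and surrogate predictions far outside the training
  region are meaningless. Convergence is declared at gap ≤ 1e−4 E_h.

## Regression

One independent scalar kernel ridge model per field (no multi-output
co-kriging), matching the framing of the method as learning the set
{ω, c_i}. The dual system (K + λI)α = y is solved by Cholesky
factorization; duplicate rows at λ = 0 raise an error suggesting λ > 0.
Kernels: RBF exp(−d²/2ℓ²) (the default — the learned fields are C^∞) and
Matérn-1/2 exp(−d/ℓ) as the C⁰ baseline choice for direct-energy fits.
Hyperparameters are either fixed or selected by seeded k-fold (default
k = 5) grid search minimizing cross-validation MAE, ties broken toward the
larger lengthscale then larger regularization. The direct-energy mode fits
the sorted adiabatic energies per level — the only representation
available without couplings — and exists as the comparison baseline; its
characteristic failure (avoided crossings in place of CIs) is asserted in
the tests rather than worked around.

When predicted CP coefficients fall off the manifold realizable by a real
spectrum (companion eigenvalues with |Im| > 1e−8 relative), the real parts
are kept and the point flagged in the prediction metadata instead of
failing: regression error near the seam routinely produces slightly
unrealizable coefficient combinations.

## Synthetic data generator

The generator produces linear vibronic coupling models
V(x) = (s·x)I + Σ_k x_k W_k with symmetric traceless W_k — the minimal
analytic form exhibiting a CI, and the same functional form used to define
the two-state cone parameters, so ground truth for (g̃, h̃, s_x, s_y), the
branching rank, and all fields is available in closed form
(c_{n−2}(x) = −Tr(M(x)²)/2 with M = Σ x_k W_k; Hessian −Tr(W_k W_l)).
Training sets are Latin hypercube samples (scipy's implementation) with
default bounds ±0.25 per coordinate around the intersection, mirroring how
geometries are drawn around minimum-energy crossing points; 2000 points
for two-dimensional studies and 3000 for the seven-dimensional three-state
study. Random models draw coupling scales uniformly from [0.1, 1.0] on a
fixed deterministic basis of the traceless symmetric space (off-diagonal
pairs first, then adjacent diagonal differences) so a requested branching
rank selects a reproducible subspace; tilts are uniform in ±0.2 by
default. No noise is added by default — the intended data source is
deterministic electronic-structure energies — but seeded Gaussian noise is
available for regularization studies.

What the generator does **not** emulate: real ab initio energies (basis-set
and active-space artifacts, anharmonicity away from the expansion point),
curved seams (a linear model's seam is a linear subspace), and molecular
conformational diversity. Passing tests therefore demonstrate the
correctness and the qualitative claims of the machinery (smoothness,
invariance, branching-space recovery, avoided-crossing contrast,
extrapolation advantage) on exactly representable ground truth, not
chemical accuracy on any particular molecule.

## Descriptors

Abstract model coordinates pass through unchanged. Molecular Cartesians
map to a reduced power-spectrum descriptor: per atomic center, the
neighbor density of each species is expanded in n_max Gaussian radial
bumps (width `sigma_atom`, equispaced centers in [0, r_cut], smooth cosine
cutoff) times real spherical harmonics up to l_max, and contracted over
the magnetic index, p_{(sn),(s'n')}^l = Σ_m c_{snlm} c_{s'n'lm}. The
contraction makes rotation/translation invariance exact; averaging over
centers adds permutation invariance of like atoms. Defaults r_cut = 5 Å,
n_max = 6, l_max = 4, sigma_atom = 0.5 Å follow common practice for
smooth-overlap-type descriptors and are fully overridable; descriptor
parameters are treated as free configuration (selected, if desired, by the
same grid-search machinery as the kernel hyperparameters).

## Study conditions and problem sizes

The end-to-end checks in `tests/test_acceptance.py` and
`scripts/acceptance.py` run at fixed conditions chosen once: the symmetric
tilted two-state cone g̃ = h̃ = 0.5, s_x = 0.25, s_y = 0.1; 2000 training
points in [−0.25, 0.25]²; RBF kernel, lengthscale 0.3 (≈ half the domain
diagonal), ridge 1e−10 (noiseless data); a three-state, seven-coordinate,
branching-rank-5 model with 3000 training points and lengthscale 0.5 (the
sparser 7-D sampling favors a slightly longer scale); gap scans on 201
points through the intersection; extrapolation measured on a ring of
radius 0.4, 1.6× the training radius.

## Known limitations

* Cone-topography parameters (g̃, h̃, s_x, s_y) are defined and implemented
  for two-state intersections only; three-state topography is limited to
  the branching/seam split.
* Direct-energy fits with the smooth RBF kernel are conditioning-limited:
  the kinked targets excite the near-null modes of the Gram matrix, so
  training-point reproduction plateaus around 1e−3 E_h where the smooth
  ω-CP targets reach 1e−6. This is a property of the baseline being
  benchmarked, not of the ω-CP path.
* The squared-gap structure of c_{n−2} means its Hessian scales with the
  square of the coupling strengths; very weak couplings (≲0.03 in the
  model units) approach the seam threshold and would need a smaller
  threshold or larger training sets.
* Learned fields are scalars; nonadiabatic coupling vectors and
  diabatization are out of scope by design.
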