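# omegacp

Machine-learned surrogates of potential energy surfaces near **seams of
conical intersection**, built on the average-energy / characteristic-polynomial
(ω-CP) decomposition of the potential matrix.

## The problem

Adiabatic potential energy surfaces E₁(R) ≤ … ≤ Eₙ(R) of a molecule are
only C⁰ across a conical intersection (CI) seam: at the seam the surfaces
touch and their derivatives jump. Standard regression of the surfaces
themselves (kernel methods, neural networks) therefore smooths the double
cone into an **avoided crossing** and misrepresents both the topography and
the dimensionality of the branching space. This matters to anyone building
surrogate potentials for photochemistry or nonadiabatic dynamics.

## The method

Decompose the n×n adiabatic potential matrix into an average energy and a
traceless splitting part,

```
V(R) = ω(R)·I + Z(R),      ω = Tr V / n,      Z_ii = E_i − ω,
```

and represent Z by the coefficients of its characteristic polynomial

```
det(λI − Z) = λⁿ + c_{n−1} λ^{n−1} + … + c_1 λ + c_0 ,    c_{n−1} ≡ 0.
```

The n quantities {ω, c_0, …, c_{n−2}} are **smooth** functions of the
nuclear coordinates everywhere — including across CI seams — and invariant
to the choice of electronic basis. They are what `omegacp` learns (kernel
ridge regression, RBF kernel; raw model coordinates or an invariant
power-spectrum descriptor for molecular Cartesians). Adiabatic energies are
recovered as eigenvalues of the companion matrix of the learned polynomial.

Two identities make the representation powerful:

* `c_{n−2} = −(1/2n) Σ_{i<j} (E_i − E_j)²` — so the Hessian of this one
  coefficient at a CI point has a column space spanning the **branching
  space** (two directions for a two-state CI, five for a three-state CI)
  and a null space spanning the **seam**.
* For a two-state cone its nonzero eigenvalues are −2g̃² and −2h̃², where g̃
  and h̃ are the norms of the orthogonalized gradient-difference and
  derivative-coupling vectors; the tilt parameters follow as s_x = ∇ω·x̂,
  s_y = ∇ω·ŷ. The full first-order cone topography comes from a single
  fitted scalar field.

## Worked example

`examples/02_fit_surrogate.py` samples 2000 Latin-hypercube geometries in
[−0.25, 0.25]² around the intersection of the two-state model
V = (0.25x + 0.1y)·I + [[0.5x, 0.5y], [0.5y, −0.5x]] and fits both an ω-CP
and a conventional direct-energy surrogate to the same data:

```
omega_cp  minimum gap on the scan: 3.68e-04 E_h at x = +0.000
direct    minimum gap on the scan: 2.60e-02 E_h at x = +0.000
-> the direct fit produces an artificial avoided crossing; the omega-CP fit
   reproduces the degeneracy.

omega_cp  MAE at radius 0.4 (trained on <= 0.25): 1.94e-04 E_h
direct    MAE at radius 0.4 (trained on <= 0.25): 1.18e-01 E_h
```

The direct fit leaves a spurious 26 mE_h gap at the intersection and loses
all predictive power outside the training region; the ω-CP surrogate closes
the gap to the fit-noise level and extrapolates to 1.6× the training radius
with sub-mE_h error, because ω and c₀ vary on much longer length scales
than the cone-shaped surfaces. `examples/03_cone_topography.py` then reads
the cone parameters off a surrogate of an asymmetric tilted cone
(g̃ = 0.213, h̃ = 0.125, s_x = −0.130, s_y = −0.046 E_h/Å):

```
 theta_x   theta_y        g~        h~       s_x       s_y
  0.0000    0.0000    0.2130    0.1250   -0.1300   -0.0460
```

i.e. quantitative recovery of the pitch, tilt and branching-plane
orientation from fitted fields alone. The other examples cover the exact
algebra (`01`) and molecular descriptors / extended-XYZ I/O (`04`).

A thin CLI wraps the same calls:

```
omegacp --config run.yaml simulate --output train.csv
omegacp --config run.yaml fit --dataset train.csv --output ens.npz
omegacp analyze --ensemble ens.npz --point 0,0
```

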