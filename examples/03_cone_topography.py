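"""Branching space and cone topography from the Hessian of c_{n−2}.

The single coefficient c_{n−2} carries all branching-space information:
its Hessian at an intersection point has one nonzero eigenvalue per
branching direction (−2g̃² and −2h̃² for a two-state cone) and a null
space spanning the seam. The tilt parameters are projections of ∇ω on the
branching unit vectors. Shown on an asymmetric two-state model (analytic
and fitted), then on a three-state model whose branching dimension is 5,
and finally a penalty-function search for the crossing point itself.
"""

import numpy as np

import omegacp as o
from omegacp.topography import cnm2_field, hessian_cnm2, split_branching_seam

# asymmetric tilted cone with realistic magnitudes (E_h/A scale)
model = o.first_order_two_state(0.213, 0.125, -0.130, -0.046)
report = o.cone_parameters(model, ci_point=[0.0, 0.0])
print("analytic model:")
print(report.table())

coords = o.latin_hypercube(2, 2000, (-0.25, 0.25), seed=4)
ens = o.fit_ensemble(
    o.make_dataset(model, coords),
    o.DescriptorConfig(mode="raw"),
    "omega_cp",
    o.HyperparamPolicy(kernel="rbf", lengthscale=0.3, regularization=1e-10),
)
fitted = o.cone_parameters(ens, [0.0, 0.0], reference_branching=np.eye(2))
print("\nsurrogate fitted to 2000 points (theta = angle to true branching plane):")
print(fitted.table())

# three-state intersection in 7 coordinates: branching dimension is 5
m3 = o.random_linear_vibronic(n_states=3, dim=7, branching_rank=5, seed=11)
split = split_branching_seam(hessian_cnm2(cnm2_field(m3), np.zeros(7), 1e-3))
print(f"\n3-state model Hessian eigenvalues: "
      f"{np.array2string(split.eigenvalues, precision=3)}")
print(f"branching dimension {split.branching_dim}, "
      f"seam dimension {split.seam_values.size}")

# locate the crossing point from a displaced start
res = o.locate_meci(model, start=[0.1, 0.1])
print(f"\nMECI search from (0.1, 0.1): point = {np.round(res.point, 6)}, "
      f"gap = {res.gap:.1e} E_h, converged = {res.converged}")
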