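"""The ω-CP decomposition: energies → smooth invariants → energies.

Takes a set of adiabatic energies, splits it into the average energy ω and
the characteristic-polynomial coefficients of the traceless splitting
matrix, and recovers the energies through the companion matrix. Also shows
the two algebraic facts the whole method rests on: c_{n−2} is a negative
sum of squared energy gaps, and the coefficients do not change under an
orthogonal change of electronic basis.
"""

import numpy as np

import omegacp as o

energies = np.array([-0.02, 0.013, 0.051])  # Hartree, three states
rec = o.energies_to_cp(energies)
print(f"energies (E_h):       {energies}")
print(f"omega (E_h):          {rec.omega:.6f}")
print(f"CP coefficients:      c_0 = {rec.coeffs[0]:.3e}, c_1 = {rec.coeffs[1]:.3e}")

back = o.cp_to_energies(rec)
print(f"reconstructed:        {back}  (companion-matrix eigenvalues + omega)")

# c_{n-2} equals -(1/2n) * sum of squared gaps: zero only at full degeneracy
print(f"squared-gap identity: {o.gap_sum_identity(energies):.3e} == c_1")

# invariance to the electronic-basis choice (adiabatic vs diabatic)
rng = np.random.default_rng(0)
from scipy.stats import ortho_group

v = np.diag(energies)
q = ortho_group.rvs(3, random_state=1)
print(f"basis-invariant:      {o.cp_invariance_check(v, q)} "
      "(same coefficients after an orthogonal similarity transform)")
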