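"""Fit ω-CP and direct-energy surrogates to the same intersection data.

Samples 2000 Latin-hypercube geometries around the conical intersection of
a symmetric tilted two-state cone (g̃ = h̃ = 0.5 E_h, s_x = 0.25,
s_y = 0.1 E_h per unit coordinate), fits kernel ridge models of the smooth
fields (ω, c_0) and of the raw adiabatic energies, then scans through the
intersection. The direct-energy surrogate leaves an avoided crossing; the
ω-CP surrogate closes the gap. It also extrapolates far better beyond the
training region, because ω and c_0 vary on much longer length scales than
the cone-shaped adiabatic surfaces.
"""

import numpy as np

import omegacp as o

model = o.first_order_two_state(0.5, 0.5, 0.25, 0.1)
coords = o.latin_hypercube(dim=2, n_samples=2000, bounds=(-0.25, 0.25), seed=1)
dataset = o.make_dataset(model, coords)

descriptor = o.DescriptorConfig(mode="raw")
policy = o.HyperparamPolicy(kernel="rbf", lengthscale=0.3, regularization=1e-10)
surrogates = {
    mode: o.fit_ensemble(dataset, descriptor, mode, policy)
    for mode in ("omega_cp", "direct")
}

# scan along the steep branching direction, straight through the intersection
xline = np.column_stack([np.linspace(-0.25, 0.25, 201), np.zeros(201)])
for mode, ens in surrogates.items():
    scan = o.gap_scan(ens, xline)
    print(f"{mode:9s} minimum gap on the scan: {scan.min_gap:.2e} E_h "
          f"at x = {scan.min_gap_point[0]:+.3f}")
print("-> the direct fit produces an artificial avoided crossing; "
      "the omega-CP fit reproduces the degeneracy.\n")

# extrapolation: query on a ring of radius 0.4, well outside the fit range
theta = np.linspace(0, 2 * np.pi, 73)
ring = 0.4 * np.column_stack([np.cos(theta), np.sin(theta)])
truth = np.array([model.energies(p) for p in ring])
for mode, ens in surrogates.items():
    mae = np.mean(np.abs(o.predict_energies(ens, ring).energies - truth))
    print(f"{mode:9s} MAE at radius 0.4 (trained on <= 0.25): {mae:.2e} E_h")
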