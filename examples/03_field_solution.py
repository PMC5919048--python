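"""Solve the nonlinear field problem for one needle-electrode protocol.

Meshes the 100 x 80 mm tissue domain with the 1-mm electrode pair 10 mm
apart, runs the Picard iteration with field-dependent Gompertz conductivity,
and prints solver diagnostics.  Uses a single moderate mesh (no refinement
study) so it runs in seconds.
"""

import numpy as np

from irepf import (
    SimulationDomain,
    build_mesh,
    cervical_cancer_params,
    electrode_currents,
    solve_potential,
)

v0 = 1000.0
domain = SimulationDomain(applied_voltage_v=v0)
cond = cervical_cancer_params(100.0)

mesh = build_mesh(domain, 0.5)
sol = solve_potential(mesh, v0, cond)

i_an, i_ca = electrode_currents(sol)
p = mesh.points
mid = np.argmin(np.hypot(p[:, 0] - 50.0, p[:, 1] - 40.0))

print(f"mesh: {mesh.n_elements} elements, {mesh.n_nodes} nodes")
print(f"Picard iterations to |dE|/|E| < 1e-6: {sol.iterations}")
print(f"potential range: [{sol.phi.min():.2f}, {sol.phi.max():.2f}] V")
print(f"field at electrode midpoint: {sol.e_mag_node[mid]:.0f} V/cm")
print(f"peak field: {sol.e_mag_node.max():.0f} V/cm")
print(f"current balance anode/cathode: {i_an:.4f} / {i_ca:.4f} (S*V per m depth)")
print(f"conductivity range: [{sol.sigma_elem.min():.4f}, {sol.sigma_elem.max():.4f}] S/m")

print(
    "\nThe potential respects 0 <= phi <= V0, anode and cathode currents"
    "\nbalance to machine precision, and conductivity saturates from the"
    "\nbaseline 0.2297 S/m toward 0.6432 S/m where the field is strong --"
    "\nthe electroporation-induced rise that spreads the field outward."
)
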