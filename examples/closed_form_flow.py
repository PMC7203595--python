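"""Check both hydraulic solvers against closed-form solutions.

Fixture 1 — a sealed chain of N canaliculi draining into the canal: under
homogeneous compression at strain rate ε̇, the velocity in segment k
(counted from the sealed end) is exactly ε̇·l·(k − 1/2), because each
segment must carry everything squeezed out of the pore volume upstream.

Fixture 2 — straight radial spokes under a 13 kPa trans-osteonal pressure
difference: every canaliculus carries the same Darcy velocity
(k_p,eff/µ)·Δp/ΔR, and node pressures decay linearly toward the canal.
"""

import numpy as np

import osteoflow as of

params = of.HydraulicParams()

chain = of.generate_chain(5, segment_length=10.0)
sol = of.solve_strain_sources(chain, params, strain_rate=0.015)
print("sealed chain, 5 segments of 10 µm, strain rate 0.015 1/s")
print("  solver velocities  :", np.round(sol.edge_velocity, 4), "µm/s")
print("  closed form        :", 0.015 * 10.0 * (np.arange(1, 6) - 0.5), "µm/s")
print(f"  canal influx {sol.boundary_flux:.6f} = strain rate x V_OLCN "
      f"{0.015 * sol.applied['V_OLCN']:.6f} µm³/s")

spoke = of.generate_spoke_osteon(100, segment_length=4.0)
sol1 = of.solve_fixed_pressure(spoke, params, delta_p=13_000.0)
v_expected = params.k_p_eff_um2 / params.mu * 13_000.0 / 68.0
print("\nspoke osteon, 100 straight radial canaliculi, 13 kPa applied")
print(f"  uniform velocity   : {np.abs(sol1.edge_velocity).mean():.4f} µm/s "
      f"(expected {v_expected:.4f})")
p = sol1.node_pressure
print(f"  pressure range     : {np.nanmin(p):.0f} .. {np.nanmax(p):.0f} Pa "
      "(canal grounded, cement line fixed)")
tau = of.shear_stress(np.abs(sol1.edge_velocity).mean(), params)
print(f"  wall shear stress  : {tau:.3f} Pa (µ·K·v; the in-vitro osteogenic "
      "band is 0.4-2 Pa)")
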