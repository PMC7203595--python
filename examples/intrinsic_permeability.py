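"""Intrinsic permeability of osteons: ideal limit vs realistic networks.

The intrinsic permeability k_osteon = v̄·µ·ΔR/Δp measures how the whole
canalicular network resists flow driven across the osteon wall.  For
perfectly straight radial canaliculi it equals the single-canaliculus
permeability k_p,eff = 1.53e-17 m²; tortuosity and detours can only lower
it.  Osteon-in-osteons, whose flow must funnel through a few bridges, come
out several times less permeable than ordinary osteons.
"""

import osteoflow as of

params = of.HydraulicParams()

spoke = of.generate_spoke_osteon(100, 4.0)
sol = of.solve_fixed_pressure(spoke, params)
k = of.intrinsic_permeability(spoke, sol, params=params)
print(f"straight spokes : k_osteon = {k.k_osteon:.3e} m²  "
      f"(= k_p,eff = {params.k_p_eff:.3e} m²)")

curled = spoke.copy()
curled.lengths = curled.lengths * 2.0  # double the arc length, same span
sol = of.solve_fixed_pressure(curled, params)
k = of.intrinsic_permeability(curled, sol, params=params)
print(f"tortuosity 2    : k_osteon = {k.k_osteon:.3e} m²  (= k_p,eff / 2)")

for label, p in [
    ("ordinary        ", of.ordinary_params(seed=1)),
    ("osteon-in-osteon", of.osteon_in_osteon_params(seed=1)),
]:
    net = of.generate_osteon(p)
    sol = of.solve_fixed_pressure(net, params)
    k = of.intrinsic_permeability(net, sol, params=params)
    print(f"{label}: k_osteon = {k.k_osteon:.3e} m²  "
          f"({k.k_osteon / params.k_p_eff:5.1%} of k_p,eff, "
          f"mean velocity {k.mean_velocity:.3f} µm/s)")
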