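"""Quasi-static hysteresis loop of the nutrient supply rate.

Sweeps phi up from 0 to 1 and back down in steps of 0.01, relaxing the
system for 1,000 time units at each step from the previous endpoint.
The B1-dominated branch survives up to phi1 = 0.7 and the B2-dominated
branch down to phi2 = 0.227: the two discontinuous transitions happen at
different supply rates, so the community composition depends on history.
"""

from phageshift import RegimeLabel, fig1_defaults, hysteresis_loop

params = fig1_defaults()
loop = hysteresis_loop(params, phi_max=1.0, dphi=0.01, t_relax=1000.0)

up = loop.up.jumps_between(RegimeLabel.F, RegimeLabel.S)
down = loop.down.jumps_between(RegimeLabel.S, RegimeLabel.F)
print(f"upward jump  (B1-dominated lost):  phi = {up[0]:.3f}")
print(f"downward jump (B2-dominated lost): phi = {down[0]:.3f}")
print(f"bistable interval: {loop.bistable_interval[0]:.3f} "
      f"to {loop.bistable_interval[1]:.3f}")

print("\nup-sweep branch (every 10th point):")
for phi, lab, st in list(zip(loop.up.phi_values, loop.up.labels,
                             loop.up.branch_states))[::10]:
    print(f"  phi={phi:.2f} {lab.value:8s} C={st[0]:.3f} "
          f"B1={st[1]:.4f} B2={st[2]:.4f} P={st[3]:.3f}")
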