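"""Closed-form analysis of the reference ecosystem.

Prints the supply-rate thresholds that organise the bifurcation diagram,
and the steady states available at phi = 0.25 (just inside the bistable
window): the B1-dominated state F, the B2-dominated state S, and the
unstable coexistence saddle that separates their basins.
"""

import numpy as np

from phageshift import (bistability_conditions, coexistence_point,
                        fig1_defaults, steady_states, thresholds)

params = fig1_defaults()
rep = bistability_conditions(params)
th = thresholds(params)
cp = coexistence_point(params)

print(f"regime: {rep.regime}")
print(f"isocline crossing (C*, P*) = ({cp.C_star:.4g}, {cp.P_star:.4g})")
print(f"thresholds: phi_B1={th.phi_B1:.4g} (bacteria can survive), "
      f"phi_P1={th.phi_P1:.4g} (phage can survive),")
print(f"            phi2={th.phi2:.4g} .. phi1={th.phi1:.4g} (bistable window)")

print("\nsteady states at phi = 0.25:")
for r in steady_states(params, 0.25):
    c = np.asarray(r.state)
    verdict = "stable" if r.stable else "unstable"
    print(f"  {r.label.value:12s} C={c[0]:.4f} B1={c[1]:.4f} "
          f"B2={c[2]:.4f} P={c[3]:.4f}  ({verdict})")

print("\nThe two stable states are alternative community compositions at "
      "identical external conditions;\nthe unstable state marks the basin "
      "boundary between them.")
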