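"""Spontaneous regime shifts under demographic noise.

Runs the event-driven (Gillespie) simulation at phi = 0.66, inside the
bistable window, starting from the B1-dominated state. Finite-size
fluctuations (population quantum 0.0002) occasionally kick the community
across the basin boundary, producing abrupt shifts between B1 and B2
dominance that the deterministic model would never make on its own.
"""

import numpy as np

from phageshift import RegimeLabel, fig1_defaults, run_stochastic, steady_states

params = fig1_defaults()
F = next(r.state for r in steady_states(params, 0.66)
         if r.label is RegimeLabel.F)

res = run_stochastic(params, F, seed=0, t_end=2000.0)
states = res.trajectory.states
B1, B2 = states[:, 1], states[:, 2]
label = np.where((B1 > 0.1) & (B2 < 0.01), "B1",
                 np.where((B2 > 0.02) & (B1 < 0.01), "B2", "-"))

print(f"events simulated: {int(res.event_counts.sum()):,}")
occ = label[label != "-"]
shifts = np.flatnonzero(occ[1:] != occ[:-1])
print(f"time in B1-dominated state: {(label == 'B1').mean():.0%}")
print(f"time in B2-dominated state: {(label == 'B2').mean():.0%}")
print(f"regime shifts observed in t=2000: {len(shifts)}")
print("\nEach shift is an abrupt community turnover at fixed external "
      "conditions —\nthe stochastic fingerprint of alternative stable states.")
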