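"""Switching the community with a one-time population pulse.

A pulse instantaneously adds to one pool (here B1, added to the
B2-dominated state) and the system then relaxes for 1,000 time units.
The scan over supply rate and pulse size shows that switching back to B1
dominance is possible only for phi below about 0.46 — well short of the
bistable window's upper edge at 0.7 — and that an oversized pulse can
overshoot and fail.
"""

import numpy as np

from phageshift import (PulseSpec, RegimeLabel, apply_pulse, fig1_defaults,
                        scan, switching_boundary)

params = fig1_defaults()

grid = scan(params, RegimeLabel.S, "B1",
            phi_values=np.round(np.arange(0.40, 0.50, 0.01), 10),
            magnitudes=np.geomspace(0.05, 2.0, 60))
print(f"largest phi where a B1 pulse (up to 2x the target-state "
      f"abundance) switches S -> F: {switching_boundary(grid, 'max_phi')}")

print("\noversized pulses overshoot (phi = 0.44):")
for mag in (0.5, 1.0, 2.0, 4.0, 6.0):
    lab = apply_pulse(params, 0.44, RegimeLabel.S, PulseSpec("B1", mag))
    print(f"  pulse {mag:4.1f} x B1(F)  ->  {lab.value}")
print("\nToo much B1 depletes the nutrient, crashes, and leaves enough "
      "phage behind for B2 to recover.")
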