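"""Phage therapy against an abortive-infection-protected pathogen.

With perfect abortive infection (beta1 = 0) the fast grower B1 kills
every phage that enters it without releasing progeny, so no nutrient
level and no single-species pulse can dislodge it. Seeding the slower,
phage-producing competitor B2 *together with* its phage establishes the
B2-phage state and eliminates B1 — the joint-pulse therapy scenario.
These runs use no species floor: the point is what happens when the
added species are genuinely absent beforehand.
"""

import math

from phageshift import (PulseSpec, RegimeLabel, apply_pulse, combined_pulse,
                        fig1_defaults, thresholds)

params = fig1_defaults().replace(beta1=0.0)
th = thresholds(params)
print(f"upper window edge with abortive infection: phi1 = {th.phi1} "
      f"(B1 never lost to rising nutrient)")
assert math.isinf(th.phi1)

phi = 0.4
for var in ("B2", "P"):
    outcomes = {apply_pulse(params, phi, RegimeLabel.B1_ONLY,
                            PulseSpec(var, mag), floor=None).value
                for mag in (0.5, 2.0, 8.0, 30.0)}
    print(f"single {var} pulses (0.5-30x): outcomes {sorted(outcomes)}")

lab = combined_pulse(params, phi, RegimeLabel.B1_ONLY,
                     [PulseSpec("B2", 5.0), PulseSpec("P", 5.0)], floor=None)
print(f"joint (B2, P) pulse at 5x: outcome {lab.value}")
print("\nOnly the combination of the competitor and its phage converts "
      "the ecosystem\n(possible for any phi above the lower window edge "
      f"phi2 = {th.phi2:.4g}).")
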