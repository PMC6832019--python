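# Methods

## Model and assumptions

The dynamical system couples one limiting nutrient (C), two bacterial
species (B1, B2) and one virulent phage (P) under mass-action kinetics
in a well-mixed environment with constant nutrient supply φ and
first-order dilution/death of every pool. All quantities are
dimensionless model units; no unit-conversion layer is provided. Growth
of species *i* is λᵢC, nutrient consumption is growth divided by the
yield Yᵢ (so the ambiguous "C(λYB)" consumption term is implemented as
C·λᵢBᵢ/Yᵢ — the only reading consistent with yield as biomass per
nutrient, verified against the closed-form nutrient level of the
B1-dominated state). Infection is mass action ηᵢBᵢP; each lysis releases
βᵢ phage. β = 0 with η > 0 is the perfect abortive-infection limit and
is supported throughout.

State vectors are ordered (C, B1, B2, P) everywhere, including file
output.

## Closed forms

All analytic results reduce to the zero-net-growth-isocline geometry:

* coexistence point: solve λ₁C − η₁P = δ_B, λ₂C − η₂P = δ_B as a 2×2
  linear system (Cramer's rule; parallel isoclines raise a
  degenerate-geometry error rather than returning garbage);
* thresholds: φ_B1 = δ_Cδ_B/λ₁ (abiotic→B1), φ_P1 = φ_B1(1 +
  (δ_P/δ_C)·λ₁/(Y₁β₁η₁)) (phage persistence on B1), and the window
  edges φ⁽ⁱ⁾ = C\*·δ_P·(λᵢ/(Yᵢβᵢηᵢ) + δ_C/δ_P). Whenever βη = 0 the
  corresponding thresholds are +∞ (abortive infection); comparisons in
  the bistability test are cross-multiplied so zero rates never divide;
* coexistence abundances at (C\*, P\*): intersection of the phage
  balance β₁η₁B₁ + β₂η₂B₂ = δ_P with the nutrient balance λ₁B₁/Y₁ +
  λ₂B₂/Y₂ = φ/C\* − δ_C, solved numerically as a 2×2 system. Inside the
  bistable window this state is the saddle; with the stoichiometry
  ordering reversed it is the stable coexistence state. The same
  formulas reproduce the linear-in-φ saddle abundances exactly.

The three δ's are kept distinct even though the reference set has them
equal: δ_P enters bacterial abundances (phage balance), δ_C the nutrient
equations and δ_B the isoclines.

Steady-state enumeration returns only uninvadable states by default
(`include_invadable=True` lifts this), each with the eigenvalues of the
analytic Jacobian. Stability demands every real part below −1e−9;
anything within ±1e−9 of the axis is flagged marginal and never reported
stable.

Known discrepancy: the source tabulation of the B2-dominated state at
φ = 0.25 (C ≈ 1.277, P ≈ 5.476) is inconsistent with its own defining
formulas, which give C ≈ 1.103, P ≈ 4.549 (the tabulated pair would
correspond to φ ≈ 0.29); the formulas are implemented.

## Deterministic integration and the species floor

The integrator is a Dormand–Prince 5(4) adaptive stepper compiled with
numba (relative tolerance 1e−8, absolute 1e−10, PI-free step control
clipped to [0.2, 5]). It was written in-package for two reasons: the
species floor must act *inside* the integration loop (after every
accepted step), and the control scans run ~10⁴ independent
1,000-time-unit integrations, which need a compiled kernel to stay at
desk scale. The stepper is cross-checked against scipy's LSODA (floor
off) in the test suite to 1e−6.

The floor (default 4e−4) models a constant weak influx of every
biological species: B1, B2 and P are clamped up to it after every
accepted step, and a species sitting at the floor with negative net
growth keeps a zero derivative inside the stage evaluations (the influx
exactly balances its losses) — without the latter, sub-floor dips within
a step act as a persistent forcing that rattles weakly damped spirals
and leaves an artificial residual oscillation. C is never floored, only
kept non-negative. Initial states are clamped too (the influx exists at
t = 0).

Two floor-induced biases are worth knowing. First, the branch states of
a floored run differ from the ideal (floor-free) steady states by order
β₂η₂·floor/δ_P ≈ 1% — a species pinned at 4e−4 with burst size 40 still
contributes to the phage balance (e.g. the B1-branch plateau sits at
0.494 rather than 0.500). Second, near the phage-onset transcritical
point the relative bias exceeds the 5% classification tolerance, so a
narrow band of supply rates (φ ≈ 0.14–0.16 for the reference set)
classifies as OTHER; onset detection in sweeps therefore reads the
phage's rise above 10× the floor rather than requiring an exact state
match.

Classification matches a converged endpoint against the analytic steady
states by relative L∞ distance with threshold 0.05 (far below the
contrast between the alternative states, generous to integrator
residue); components at or within a factor 2 of the floor count as
absent. Near a fold the saddle approaches a stable state within the
tolerance, so stable candidates win ties — a converged endpoint belongs
to an attractor.

## Stochastic simulation

The exact stochastic simulation algorithm runs on populations quantized
in units of Δ = 0.0002: each of the nine elementary processes (supply,
nutrient dilution, two replications, two infections, two bacterial
deaths, phage decay) fires with propensity equal to its deterministic
flux divided by Δ and moves one quantum (replication also consumes Δ/Y
nutrient; infection of species *i* converts one bacterial quantum into
βᵢ phage quanta). This makes the propensity-weighted sum of the event
effects identically equal to the deterministic right-hand side — the
drift identity, asserted at 1,000 random states in the suite — and the
ensemble mean of short runs agrees with the ODE within Monte-Carlo
error. The floor is enforced by clamping after every event. The RNG is
seeded inside the compiled kernel; a given seed reproduces a run
bitwise.

At φ = 0.66 the reference ecosystem shows spontaneous shifts between the
two alternative states on a 10²–10³ time-unit scale: a pilot of five
seeds at t = 2,000 (about 4×10⁷ events each) always contained shifts in
both directions, and those batch sizes are what the tests and examples
use.

## Sweep protocol

Quasi-static sweeps step φ on a grid (default Δφ = 0.01), integrating
1,000 time units per point with the floor on, warm-starting each point
from the previous endpoint; the very first point starts from
(C = φ/δ_C, floor, floor, floor). Grid points still mid-transient after
t_relax — classification OTHER or off-floor residual above 1e−4, the
signature of critical slowing down near a jump — are relaxed for up to
three further periods; still-unconverged points are flagged, not fatal.
Jumps are reported as midpoints of the grid interval where the label
changes, i.e. localized to one grid step, never interpolated.

## Pulse protocol

A pulse adds a fixed amount to one pool (or several simultaneously) of
an analytic stable state, then relaxes 1,000 time units with the floor
on and classifies. Magnitudes are expressed by default as multiples of
the pulsed variable's value in the *target* stable state at the same φ
(raw units also available). Default grids: φ on the 0.01 grid strictly
inside the bistable window; 200 log-spaced magnitudes from 0.01× with
caps of 2× for the B1-pulse scan and 3× for the P-pulse scan. With these
protocols the B1-pulse switching bound computes to φ = 0.46 and the
P-pulse success region begins at φ = 0.32 (insensitive to raising the
magnitude cap to 100×, to implementing the floor as an explicit influx
term, or to extending the relaxation: below that the post-pulse state
returns exactly to the B1-dominated fixed point). A joint B2-pulse scan
reaches down to φ ≈ 0.26–0.27 at magnitudes near 8×. Oversized B1 pulses
fail reentrantly (e.g. at φ = 0.44 the success window is ≈1.4×–4.7×),
which is why the reentrance check scans an extended magnitude range.

The abortive-infection scenario (β₁ = 0) is run with the floor *off*:
the floor's 4e−4 seed of an absent pool would itself act as a second
pulse and let single-variable pulses succeed trivially. With truly
absent pools, no single B2 or P pulse of any size eliminates B1, while
joint (B2, P) pulses do for supply rates above the lower window edge
(success pockets exist at moderate magnitudes; very large joint pulses
overshoot and fail, like oversized B1 pulses).

## Numerical choices and degenerate inputs

* Integrator: rtol 1e−8, atol 1e−10, initial step 1e−3, fixed-point
  early stop at off-floor residual < 1e−10 (used by sweeps and scans;
  leaves converged endpoints unchanged by construction).
* Eigenvalue stability band ±1e−9; classification tolerance 0.05;
  absent-species threshold 2× floor.
* Parallel isoclines, non-positive coexistence points, zero β or η, and
  frozen stochastic states (zero total propensity) are all reported
  explicitly (errors, None fields, or a `halted` flag) rather than
  silently propagating NaN or inf.
* Negative state components are rejected at the API boundary; the
  stochastic kernel clamps C at 0 after dilution events since C < Δ can
  occur.

## What the tests do and do not show

The whole study is synthetic: the model *is* the object of interest and
there is no external data. Passing tests show that the implementation
reproduces the model's closed forms, that the three dynamical engines
(closed-form, ODE, SSA) agree with each other where they must, and that
the sweep and pulse protocols recover the bifurcation structure. They
say nothing about how faithfully this four-variable mean-field model
describes any real phage–bacterium community (no spatial structure,
single nutrient, no lysogeny, no evolution of resistance — all out of
scope by design).

## Limitations

* The floor biases floored branches by ~1% (quantified above); results
  quoted at three digits refer to the floor-free closed forms.
* Sweep and pulse boundary localization is limited to the φ grid step
  (0.01).
* The SSA is exact but unaccelerated (no tau-leaping); runs much beyond
  ~10⁸ events per trajectory become minutes-scale.
* Near-threshold dynamics (transcritical onsets, fold points) converge
  slowly; the protocols handle this by extension-and-flag rather than by
  adaptive continuation.
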