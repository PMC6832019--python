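"""Closed-form steady states, regime boundaries and bistability analysis.

Everything here follows from the zero-net-growth-isocline (ZNGI) geometry
of the model: species i can hold a steady population exactly on the line
lambda_i·C − eta_i·P = deltaB in the (C, P) plane of environmental
conditions. The two ZNGIs cross at a single point (C*, P*), the only
environment in which the two bacteria can coexist; whether that
coexistence is dynamically stable or a saddle separating two alternative
stable states is decided by the growth/susceptibility/stoichiometry
orderings evaluated by :func:`bistability_conditions`.

Four supply-rate thresholds organise the bifurcation diagram:

* ``phi_B1`` — below it the environment is abiotic;
* ``phi_P1`` — above it the phage persists on B1 alone;
* ``phi1``   — supply rate at which the B1-dominated environment reaches
  (C*, P*) and becomes invadable by B2 (upper end of the bistable window);
* ``phi2``   — same for the B2-dominated environment (lower end).

Under the bistability conditions the window phi2 < phi < phi1 holds two
alternative stable states, F (B1 + phage) and S (B2 + phage), separated
by a dynamically unstable coexistence state at (C*, P*).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .model_core import EcoState, ModelParams, RegimeLabel, jacobian, rhs

__all__ = [
    "CoexistencePoint",
    "Thresholds",
    "BistabilityReport",
    "SteadyStateReport",
    "CrossPoints",
    "DegenerateGeometryError",
    "NotBistableError",
    "coexistence_point",
    "thresholds",
    "bistability_conditions",
    "phage_persistence_in_F",
    "steady_states",
    "hysteresis_jump_states",
]

#: eigenvalue real parts within this band of zero are "marginal"
STABILITY_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """The two ZNGIs are parallel; no unique coexistence point exists."""


class NotBistableError(ValueError):
    """Operation requires a parameter set satisfying the bistability conditions."""


@dataclasses.dataclass(frozen=True)
class CoexistencePoint:
    """Intersection (C*, P*) of the two bacterial ZNGIs."""

    C_star: float
    P_star: float

    @property
    def is_positive(self) -> bool:
        return self.C_star > 0 and self.P_star > 0


@dataclasses.dataclass(frozen=True)
class Thresholds:
    """Nutrient-supply-rate boundaries of the bifurcation diagram.

    ``phi1``/``phi2`` are +inf when the corresponding bacterium produces
    no phage (beta·eta = 0, perfect abortive infection), and None when no
    positive coexistence point exists (the window is then undefined).
    """

    phi_B1: float
    phi_P1: float
    phi1: float | None
    phi2: float | None


@dataclasses.dataclass(frozen=True)
class BistabilityReport:
    """Outcome of the three bistability inequalities.

    regime is 'bistable' when B1 grows faster, B2 is less susceptible per
    unit growth, and B2 converts nutrient to phage more efficiently
    (growth_ordering, susceptibility_ordering, stoichiometry_ordering all
    True); 'stable_coexistence' when the stoichiometry ordering is
    reversed; 'neither' otherwise.
    """

    regime: str
    growth_ordering: bool
    susceptibility_ordering: bool
    stoichiometry_ordering: bool


@dataclasses.dataclass(frozen=True)
class SteadyStateReport:
    """One steady state with its linear-stability verdict.

    stable is True only when every eigenvalue real part is < −1e-9;
    marginal flags eigenvalues within ±1e-9 of the imaginary axis (such
    states are never reported as stable).
    """

    label: RegimeLabel
    state: EcoState
    eigenvalues: np.ndarray
    stable: bool
    marginal: bool


@dataclasses.dataclass(frozen=True)
class CrossPoints:
    """(C, P) landed on just past each end of the hysteresis loop."""

    C1x: float
    P1x: float
    C2x: float
    P2x: float


def coexistence_point(params: ModelParams) -> CoexistencePoint:
    """Solve the 2x2 linear system of the two ZNGIs.

        lambda1·C − eta1·P = deltaB
        lambda2·C − eta2·P = deltaB

    Raises DegenerateGeometryError when the lines are parallel. A
    non-positive intersection is returned as-is; callers check
    ``is_positive`` (no positive coexistence point).
    """
    det = -params.lambda1 * params.eta2 + params.lambda2 * params.eta1
    norm = max(params.lambda1 * params.eta2, params.lambda2 * params.eta1, 1e-300)
    if abs(det) <= 1e-12 * norm:
        raise DegenerateGeometryError(
            "ZNGIs are parallel (lambda1·eta2 == lambda2·eta1); "
            "no unique coexistence point"
        )
    # Cramer's rule on [[l1, -e1], [l2, -e2]] x = [dB, dB]
    C = params.deltaB * (params.eta1 - params.eta2) / det
    P = params.deltaB * (params.lambda1 - params.lambda2) / det
    return CoexistencePoint(C, P)


def _inv_conversion(params: ModelParams, species: int) -> float:
    """lambda/(Y·beta·eta) for species 1 or 2; +inf when beta·eta = 0."""
    if species == 1:
        lam, Y, beta, eta = params.lambda1, params.Y1, params.beta1, params.eta1
    else:
        lam, Y, beta, eta = params.lambda2, params.Y2, params.beta2, params.eta2
    denom = Y * beta * eta
    if denom == 0:
        return math.inf
    return lam / denom


def thresholds(params: ModelParams) -> Thresholds:
    """The four supply-rate boundaries (see module docstring).

        phi_B1 = deltaC·deltaB/lambda1
        phi_P1 = phi_B1·(1 + (deltaP/deltaC)·lambda1/(Y1·beta1·eta1))
        phi1   = C*·deltaP·(lambda1/(Y1·beta1·eta1) + deltaC/deltaP)
        phi2   = C*·deltaP·(lambda2/(Y2·beta2·eta2) + deltaC/deltaP)
    """
    if params.lambda1 <= 0:
        raise ValueError("thresholds require lambda1 > 0")
    phi_B1 = params.deltaC * params.deltaB / params.lambda1
    inv1 = _inv_conversion(params, 1)
    inv2 = _inv_conversion(params, 2)
    if math.isinf(inv1) or params.deltaC == 0:
        phi_P1 = math.inf
    else:
        phi_P1 = phi_B1 * (1.0 + (params.deltaP / params.deltaC) * inv1)
    try:
        cp = coexistence_point(params)
    except DegenerateGeometryError:
        return Thresholds(phi_B1, phi_P1, None, None)
    if not cp.is_positive:
        return Thresholds(phi_B1, phi_P1, None, None)
    phi1 = math.inf if math.isinf(inv1) else cp.C_star * (params.deltaP * inv1 + params.deltaC)
    phi2 = math.inf if math.isinf(inv2) else cp.C_star * (params.deltaP * inv2 + params.deltaC)
    return Thresholds(phi_B1, phi_P1, phi1, phi2)


def bistability_conditions(params: ModelParams) -> BistabilityReport:
    """Evaluate the three orderings that decide bistability.

    Implemented by cross-multiplication so beta = 0 or eta = 0 (abortive
    infection / full resistance) never divides by zero.
    """
    growth = params.lambda1 > params.lambda2
    suscept = params.lambda1 * params.eta2 < params.lambda2 * params.eta1
    # lambda1/(Y1 b1 e1) > lambda2/(Y2 b2 e2), cross-multiplied
    lhs = params.lambda1 * params.Y2 * params.beta2 * params.eta2
    rhs_ = params.lambda2 * params.Y1 * params.beta1 * params.eta1
    stoich = lhs > rhs_
    if growth and suscept and stoich:
        regime = "bistable"
    elif growth and suscept and lhs < rhs_:
        regime = "stable_coexistence"
    else:
        regime = "neither"
    return BistabilityReport(regime, growth, suscept, stoich)


def phage_persistence_in_F(params: ModelParams) -> bool:
    """True when the phage is present in *both* alternative states across
    the bistable window, i.e. phi2 > phi_P1."""
    th = thresholds(params)
    if th.phi2 is None:
        return False
    return th.phi2 > th.phi_P1


def _report(label: RegimeLabel, state: EcoState, params: ModelParams,
            phi: float) -> SteadyStateReport:
    eig = np.linalg.eigvals(jacobian(state, params, phi=phi))
    max_re = float(np.max(eig.real))
    marginal = abs(max_re) <= STABILITY_TOL
    stable = (max_re < -STABILITY_TOL) and not marginal
    return SteadyStateReport(label, state, eig, stable, marginal)


def coexistence_abundances(params: ModelParams, phi: float) -> tuple[float, float] | None:
    """Bacterial abundances (B1, B2) at the ZNGI crossing for supply rate phi.

    Solves the phage balance beta1·eta1·B1 + beta2·eta2·B2 = deltaP
    together with the nutrient balance lambda1·B1/Y1 + lambda2·B2/Y2 =
    phi/C* − deltaC. Returns None when either abundance is non-positive
    or the system is singular.
    """
    try:
        cp = coexistence_point(params)
    except DegenerateGeometryError:
        return None
    if not cp.is_positive:
        return None
    A = np.array([
        [params.beta1 * params.eta1, params.beta2 * params.eta2],
        [params.lambda1 / params.Y1, params.lambda2 / params.Y2],
    ])
    b = np.array([params.deltaP, phi / cp.C_star - params.deltaC])
    if abs(np.linalg.det(A)) < 1e-14:
        return None
    B1, B2 = np.linalg.solve(A, b)
    if B1 <= 0 or B2 <= 0:
        return None
    return float(B1), float(B2)


def steady_states(params: ModelParams, phi: float,
                  include_invadable: bool = False) -> list[SteadyStateReport]:
    """Enumerate the uninvadable steady states at supply rate phi.

    Candidates (each included only where its abundances are positive and,
    unless ``include_invadable``, no absent species could grow there):

    * ABIOTIC: C = phi/deltaC, everything else 0.
    * B1_ONLY / B2_ONLY: one bacterium, no phage.
    * F: B1 = deltaP/(beta1·eta1), C = phi/(deltaC + lambda1·B1/Y1),
      P = (lambda1·C − deltaB)/eta1.
    * S: the same with species-2 constants.
    * COEXISTENCE: both bacteria at (C*, P*) with abundances from
      :func:`coexistence_abundances` (the dynamically unstable saddle in
      the bistable regime).

    Each report carries the Jacobian eigenvalues at the state.
    """
    if phi < 0:
        raise ValueError("phi must be >= 0")
    tol = 1e-12
    out: list[SteadyStateReport] = []

    def invasion_rate(lam: float, eta: float, C: float, P: float) -> float:
        return lam * C - eta * P - params.deltaB

    # ABIOTIC
    C0 = phi / params.deltaC if params.deltaC > 0 else math.inf
    if math.isfinite(C0):
        uninvadable = (invasion_rate(params.lambda1, params.eta1, C0, 0.0) <= tol
                       and invasion_rate(params.lambda2, params.eta2, C0, 0.0) <= tol)
        if uninvadable or include_invadable:
            out.append(_report(RegimeLabel.ABIOTIC, EcoState(C0, 0, 0, 0), params, phi))

    # single-species, no phage
    for label, lam, Y, beta, eta, other in (
        (RegimeLabel.B1_ONLY, params.lambda1, params.Y1, params.beta1, params.eta1,
         (params.lambda2, params.eta2)),
        (RegimeLabel.B2_ONLY, params.lambda2, params.Y2, params.beta2, params.eta2,
         (params.lambda1, params.eta1)),
    ):
        if lam <= 0:
            continue
        C = params.deltaB / lam
        B = Y * (phi / C - params.deltaC) / lam
        if B <= tol:
            continue
        phage_growth = beta * eta * B - params.deltaP
        bact_growth = invasion_rate(other[0], other[1], C, 0.0)
        state = EcoState(C, B, 0, 0) if label is RegimeLabel.B1_ONLY else EcoState(C, 0, B, 0)
        if (phage_growth <= tol and bact_growth <= tol) or include_invadable:
            out.append(_report(label, state, params, phi))

    # one bacterium + phage (F and S)
    for label, lam, Y, beta, eta, other in (
        (RegimeLabel.F, params.lambda1, params.Y1, params.beta1, params.eta1,
         (params.lambda2, params.eta2)),
        (RegimeLabel.S, params.lambda2, params.Y2, params.beta2, params.eta2,
         (params.lambda1, params.eta1)),
    ):
        if beta * eta == 0 or lam <= 0:
            continue
        B = params.deltaP / (beta * eta)
        C = phi / (params.deltaC + lam * B / Y)
        P = (lam * C - params.deltaB) / eta
        if P <= tol:
            continue
        bact_growth = invasion_rate(other[0], other[1], C, P)
        if bact_growth <= tol or include_invadable:
            if label is RegimeLabel.F:
                state = EcoState(C, B, 0, P)
            else:
                state = EcoState(C, 0, B, P)
            out.append(_report(label, state, params, phi))

    # coexistence at (C*, P*)
    ab = coexistence_abundances(params, phi)
    if ab is not None:
        cp = coexistence_point(params)
        state = EcoState(cp.C_star, ab[0], ab[1], cp.P_star)
        out.append(_report(RegimeLabel.COEXISTENCE, state, params, phi))

    return out


def hysteresis_jump_states(params: ModelParams) -> CrossPoints:
    """(C, P) the environment lands on just past each end of the bistable
    window: (C2x, P2x) for the upward jump at phi1, (C1x, P1x) for the
    downward jump at phi2. Requires a bistable parameter set."""
    rep = bistability_conditions(params)
    if rep.regime != "bistable":
        raise NotBistableError(
            f"hysteresis cross points require a bistable parameter set "
            f"(got regime {rep.regime!r})"
        )
    th = thresholds(params)
    if th.phi1 is None or th.phi2 is None or math.isinf(th.phi1):
        raise NotBistableError("bistable window is unbounded or undefined")
    C2x = th.phi1 / (params.deltaC + params.deltaP * params.lambda2
                     / (params.Y2 * params.beta2 * params.eta2))
    P2x = (params.lambda2 * C2x - params.deltaB) / params.eta2
    C1x = th.phi2 / (params.deltaC + params.deltaP * params.lambda1
                     / (params.Y1 * params.beta1 * params.eta1))
    P1x = (params.lambda1 * C1x - params.deltaB) / params.eta1
    return CrossPoints(C1x=C1x, P1x=P1x, C2x=C2x, P2x=P2x)


def _self_check(params: ModelParams, phi: float) -> float:
    """Max |rhs| over all enumerated steady states (diagnostic helper)."""
    worst = 0.0
    for rep in steady_states(params, phi, include_invadable=True):
        worst = max(worst, float(np.max(np.abs(rhs(rep.state, params, phi=phi)))))
    return worst
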