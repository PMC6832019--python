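"""Event-driven stochastic simulation of the nine elementary processes.

Populations are quantized in units of a small quantum Δ (default 0.0002)
and evolved with the exact stochastic simulation algorithm (exponential
waiting times from the total propensity, categorical event choice). Each
elementary event moves one quantum: the rate of each process is the
corresponding deterministic flux divided by Δ, so rate × Δ recovers the
deterministic term and the propensity-weighted sum of event effects is
identically the deterministic right-hand side (the drift identity, tested
at random states in the suite).

The nine processes, in fixed order:

    0  nutrient supply          rate phi/Δ             C += Δ
    1  nutrient dilution        rate deltaC·C/Δ        C −= Δ
    2  B1 replication           rate lambda1·C·B1/Δ    B1 += Δ, C −= Δ/Y1
    3  B2 replication           rate lambda2·C·B2/Δ    B2 += Δ, C −= Δ/Y2
    4  phage infection of B1    rate eta1·B1·P/Δ       B1 −= Δ, P += beta1·Δ
    5  phage infection of B2    rate eta2·B2·P/Δ       B2 −= Δ, P += beta2·Δ
    6  B1 death/dilution        rate deltaB·B1/Δ       B1 −= Δ
    7  B2 death/dilution        rate deltaB·B2/Δ       B2 −= Δ
    8  phage decay              rate deltaP·P/Δ        P −= Δ

Nutrient consumption rides on the replication events (−Δ/Y on C), which
keeps the stochastic drift identical to the deterministic nutrient
balance. After every event B1, B2 and P are clamped up to the floor
(default 4e-4, a weak constant species influx) and C is kept >= 0.
"""

from __future__ import annotations

import dataclasses

import numba as nb
import numpy as np

from .model_core import EcoState, ModelParams
from .deterministic import DEFAULT_FLOOR, Trajectory

__all__ = [
    "StochasticConfig",
    "StochasticResult",
    "N_EVENTS",
    "propensities",
    "step_effects",
    "run",
]

N_EVENTS = 9
DEFAULT_QUANTUM = 2e-4


@dataclasses.dataclass(frozen=True)
class StochasticConfig:
    """Run configuration for the stochastic simulator.

    quantum is the population increment per event; floor must be at least
    one quantum so a floored population can still lose a quantum without
    going negative between clamps.
    """

    quantum: float = DEFAULT_QUANTUM
    floor: float = DEFAULT_FLOOR
    seed: int = 0
    t_end: float = 1000.0
    record_dt: float = 1.0

    def __post_init__(self) -> None:
        if self.quantum <= 0:
            raise ValueError("quantum must be > 0")
        if self.floor < self.quantum:
            raise ValueError("floor must be >= quantum")
        if self.record_dt <= 0:
            raise ValueError("record_dt must be > 0")
        if self.t_end <= 0:
            raise ValueError("t_end must be > 0")


def propensities(state: EcoState | np.ndarray, params: ModelParams,
                 quantum: float = DEFAULT_QUANTUM,
                 phi: float | None = None) -> np.ndarray:
    """The nine event rates (events per time) at `state`."""
    C, B1, B2, P = np.asarray(state, dtype=np.float64)
    if min(C, B1, B2, P) < 0:
        raise ValueError("state components must be >= 0")
    p = params if phi is None else params.with_phi(phi)
    return np.array([
        p.phi,
        p.deltaC * C,
        p.lambda1 * C * B1,
        p.lambda2 * C * B2,
        p.eta1 * B1 * P,
        p.eta2 * B2 * P,
        p.deltaB * B1,
        p.deltaB * B2,
        p.deltaP * P,
    ]) / quantum


def step_effects(params: ModelParams,
                 quantum: float = DEFAULT_QUANTUM) -> np.ndarray:
    """9x4 matrix of state increments (C, B1, B2, P) per event."""
    d = quantum
    return np.array([
        [d, 0.0, 0.0, 0.0],
        [-d, 0.0, 0.0, 0.0],
        [-d / params.Y1, d, 0.0, 0.0],
        [-d / params.Y2, 0.0, d, 0.0],
        [0.0, -d, 0.0, params.beta1 * d],
        [0.0, 0.0, -d, params.beta2 * d],
        [0.0, -d, 0.0, 0.0],
        [0.0, 0.0, -d, 0.0],
        [0.0, 0.0, 0.0, -d],
    ])


@nb.njit(cache=True)
def _ssa_core(p, y0, quantum, floor, t_end, rec_dt, seed):
    """Exact SSA loop. Returns (times, states, event_counts, t_final, y)."""
    np.random.seed(seed)
    y = y0.copy()
    for j in range(1, 4):
        if y[j] < floor:
            y[j] = floor
    t = 0.0
    nrec = int(t_end / rec_dt) + 1
    rec_t = np.empty(nrec)
    rec_y = np.empty((nrec, 4))
    rec_t[0] = 0.0
    rec_y[0] = y
    irec = 1
    counts = np.zeros(N_EVENTS, dtype=np.int64)
    rates = np.empty(N_EVENTS)
    inv_q = 1.0 / quantum

    while t < t_end:
        C, B1, B2, P = y[0], y[1], y[2], y[3]
        rates[0] = p[11] * inv_q
        rates[1] = p[8] * C * inv_q
        rates[2] = p[0] * C * B1 * inv_q
        rates[3] = p[1] * C * B2 * inv_q
        rates[4] = p[4] * B1 * P * inv_q
        rates[5] = p[5] * B2 * P * inv_q
        rates[6] = p[9] * B1 * inv_q
        rates[7] = p[9] * B2 * inv_q
        rates[8] = p[10] * P * inv_q
        total = 0.0
        for k in range(N_EVENTS):
            total += rates[k]
        if total <= 0.0:
            break  # frozen: no process can fire
        t += np.random.exponential(1.0 / total)
        if t > t_end:
            t = t_end
            break
        u = np.random.random() * total
        acc = 0.0
        ev = N_EVENTS - 1
        for k in range(N_EVENTS):
            acc += rates[k]
            if u < acc:
                ev = k
                break
        counts[ev] += 1
        if ev == 0:
            y[0] += quantum
        elif ev == 1:
            y[0] -= quantum
        elif ev == 2:
            y[1] += quantum
            y[0] -= quantum / p[2]
        elif ev == 3:
            y[2] += quantum
            y[0] -= quantum / p[3]
        elif ev == 4:
            y[1] -= quantum
            y[3] += p[6] * quantum
        elif ev == 5:
            y[2] -= quantum
            y[3] += p[7] * quantum
        elif ev == 6:
            y[1] -= quantum
        elif ev == 7:
            y[2] -= quantum
        else:
            y[3] -= quantum
        if y[0] < 0.0:
            y[0] = 0.0
        for j in range(1, 4):
            if y[j] < floor:
                y[j] = floor
        while irec < nrec and irec * rec_dt <= t:
            rec_t[irec] = irec * rec_dt
            rec_y[irec] = y
            irec += 1

    # pad remaining record slots with the final state (frozen or t_end hit)
    while irec < nrec:
        rec_t[irec] = irec * rec_dt
        rec_y[irec] = y
        irec += 1
    return rec_t, rec_y, counts, t, y


@dataclasses.dataclass
class StochasticResult:
    """Trajectory plus bookkeeping from one seeded SSA run."""

    trajectory: Trajectory
    event_counts: np.ndarray
    config: StochasticConfig
    halted: bool  # True when total propensity hit zero before t_end

    @property
    def final_state(self) -> EcoState:
        return self.trajectory.final_state


def run(params: ModelParams, init: EcoState | np.ndarray,
        config: StochasticConfig | None = None, *,
        phi: float | None = None, **overrides) -> StochasticResult:
    """Run the SSA from `init`; reproducible for a given config.seed.

    Keyword overrides (seed=, t_end=, ...) build a modified config.
    """
    if config is None:
        config = StochasticConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)
    y0 = np.asarray(init, dtype=np.float64)
    if np.any(y0 < 0):
        raise ValueError("initial state must be >= 0")
    p = params.to_array(phi=phi)
    rec_t, rec_y, counts, t_final, _ = _ssa_core(
        p, y0, config.quantum, config.floor, config.t_end,
        config.record_dt, config.seed,
    )
    traj = Trajectory(times=rec_t, states=rec_y, params=params,
                      floor=config.floor)
    return StochasticResult(trajectory=traj, event_counts=counts,
                            config=config, halted=t_final < config.t_end)
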