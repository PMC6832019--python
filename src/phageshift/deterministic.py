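"""Deterministic time integration with a species-influx floor.

The engine is an adaptive Dormand–Prince 5(4) stepper compiled with
numba. After every accepted step the three biological pools (B1, B2, P)
are clamped up to a small floor (default 4e-4) — the deterministic
counterpart of a constant weak influx of each species, which lets an
absent species re-invade as soon as its net growth rate turns positive.
The nutrient C is never floored (only kept non-negative).

A per-step clamp is a state modification in the middle of integration,
which is why the stepper is implemented here rather than through an
off-the-shelf driver; the compiled kernel also makes the large pulse and
sweep scans (tens of thousands of 1,000-time-unit integrations)
desk-scale. scipy's integrators are used in the test suite as an
independent cross-check of this stepper with the floor disabled.
"""

from __future__ import annotations

import dataclasses
import math

import numba as nb
import numpy as np
import pandas as pd

from .model_core import EcoState, ModelParams, RegimeLabel
from . import analytic

__all__ = [
    "Trajectory",
    "IntegrationError",
    "DEFAULT_FLOOR",
    "integrate",
    "relax",
    "classify",
]

DEFAULT_FLOOR = 4e-4

_STATUS_OK = 0
_STATUS_CONVERGED = 1
_STATUS_NONFINITE = 2
_STATUS_UNDERFLOW = 3
_STATUS_MAXSTEPS = 4


class IntegrationError(RuntimeError):
    pass


@nb.njit(cache=True)
def _f(y, p):
    out = np.empty(4)
    C, B1, B2, P = y[0], y[1], y[2], y[3]
    out[0] = p[11] - p[8] * C - C * (p[0] * B1 / p[2] + p[1] * B2 / p[3])
    out[1] = B1 * (p[0] * C - p[4] * P - p[9])
    out[2] = B2 * (p[1] * C - p[5] * P - p[9])
    out[3] = P * (p[6] * p[4] * B1 + p[7] * p[5] * B2 - p[10])
    return out


@nb.njit(cache=True)
def _f_floored(y, p, floor):
    """RHS with species pinned at the floor: a component sitting at (or
    below) the floor with negative net growth keeps a zero derivative —
    the weak influx exactly balances its losses until growth turns
    positive. Prevents sub-floor dips inside a step from rattling weakly
    damped spirals."""
    out = _f(y, p)
    if floor > 0.0:
        for j in range(1, 4):
            if y[j] <= floor and out[j] < 0.0:
                out[j] = 0.0
    return out


@nb.njit(cache=True)
def _step_core(p, y0, t0, t_end, floor, rtol, atol, conv_tol, rec_dt, hmax_in):
    """Adaptive DP5(4) loop with per-step floor clamp.

    Returns (status, t_final, y_final, rec_times, rec_states).
    """
    y = y0.copy()
    if floor > 0.0:
        for j in range(1, 4):
            if y[j] < floor:
                y[j] = floor
    t = t0

    nrec = 0
    if rec_dt > 0.0:
        nrec = int(math.floor((t_end - t0) / rec_dt + 1e-9)) + 1
    rec_t = np.empty(nrec)
    rec_y = np.empty((nrec, 4))
    irec = 0
    if nrec > 0:
        rec_t[0] = t
        rec_y[0] = y
        irec = 1

    hmax = hmax_in
    if rec_dt > 0.0 and rec_dt < hmax:
        hmax = rec_dt

    f0 = _f_floored(y, p, floor)
    h = 1e-3
    status = _STATUS_OK
    nsteps = 0
    max_steps = 50_000_000

    while t < t_end - 1e-12 * max(1.0, abs(t_end)):
        nsteps += 1
        if nsteps > max_steps:
            status = _STATUS_MAXSTEPS
            break
        if h > t_end - t:
            h = t_end - t
        if h > hmax:
            h = hmax

        k1 = f0
        k2 = _f_floored(y + h * (0.2 * k1), p, floor)
        k3 = _f_floored(y + h * (3.0 / 40.0 * k1 + 9.0 / 40.0 * k2), p, floor)
        k4 = _f_floored(y + h * (44.0 / 45.0 * k1 - 56.0 / 15.0 * k2 + 32.0 / 9.0 * k3), p, floor)
        k5 = _f_floored(y + h * (19372.0 / 6561.0 * k1 - 25360.0 / 2187.0 * k2
                                 + 64448.0 / 6561.0 * k3 - 212.0 / 729.0 * k4), p, floor)
        k6 = _f_floored(y + h * (9017.0 / 3168.0 * k1 - 355.0 / 33.0 * k2
                                 + 46732.0 / 5247.0 * k3 + 49.0 / 176.0 * k4
                                 - 5103.0 / 18656.0 * k5), p, floor)
        y_new = y + h * (35.0 / 384.0 * k1 + 500.0 / 1113.0 * k3
                         + 125.0 / 192.0 * k4 - 2187.0 / 6784.0 * k5
                         + 11.0 / 84.0 * k6)
        k7 = _f_floored(y_new, p, floor)
        # embedded 4th-order error
        e = h * (71.0 / 57600.0 * k1 - 71.0 / 16695.0 * k3 + 71.0 / 1920.0 * k4
                 - 17253.0 / 339200.0 * k5 + 22.0 / 525.0 * k6 - 1.0 / 40.0 * k7)
        err = 0.0
        bad = False
        for j in range(4):
            if not np.isfinite(y_new[j]):
                bad = True
                break
            sc = atol + rtol * max(abs(y[j]), abs(y_new[j]))
            r = e[j] / sc
            err += r * r
        if bad:
            h *= 0.1
            if h < 1e-13:
                status = _STATUS_NONFINITE
                break
            continue
        err = math.sqrt(err / 4.0)

        if err <= 1.0:
            t_prev = t
            y_prev = y
            t = t + h
            y = y_new
            # floor clamp (B1, B2, P); nutrient only kept non-negative
            if floor > 0.0:
                for j in range(1, 4):
                    if y[j] < floor:
                        y[j] = floor
            for j in range(4):
                if y[j] < 0.0:
                    y[j] = 0.0
            f0 = _f_floored(y, p, floor)
            # record by linear interpolation over the accepted step
            while irec < nrec:
                tk = t0 + irec * rec_dt
                if tk > t + 1e-12:
                    break
                w = (tk - t_prev) / (t - t_prev) if t > t_prev else 1.0
                rec_t[irec] = tk
                for j in range(4):
                    rec_y[irec, j] = y_prev[j] * (1.0 - w) + y[j] * w
                irec += 1
            # fixed-point stop: ignore components pinned at the floor
            if conv_tol > 0.0:
                worst = abs(f0[0])
                for j in range(1, 4):
                    if floor > 0.0 and y[j] <= floor * 1.0000001 and f0[j] < 0.0:
                        continue
                    if abs(f0[j]) > worst:
                        worst = abs(f0[j])
                if worst < conv_tol:
                    status = _STATUS_CONVERGED
                    break

        if err == 0.0:
            factor = 5.0
        else:
            factor = 0.9 * err ** -0.2
            if factor > 5.0:
                factor = 5.0
            elif factor < 0.2:
                factor = 0.2
        h *= factor
        if h < 1e-13:
            status = _STATUS_UNDERFLOW
            break

    return status, t, y, rec_t[:irec], rec_y[:irec, :]


@dataclasses.dataclass
class Trajectory:
    """Time series of (C, B1, B2, P) from an integrator run."""

    times: np.ndarray
    states: np.ndarray
    params: ModelParams
    floor: float | None = DEFAULT_FLOOR

    @property
    def final_state(self) -> EcoState:
        return EcoState.from_array(self.states[-1])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.times, "C": self.states[:, 0], "B1": self.states[:, 1],
             "B2": self.states[:, 2], "P": self.states[:, 3]}
        )


def _run(params: ModelParams, init, t_end, phi, floor, rtol, atol,
         conv_tol, rec_dt):
    y0 = np.asarray(init, dtype=np.float64)
    if y0.shape != (4,):
        raise ValueError("initial state must have 4 components (C, B1, B2, P)")
    if np.any(y0 < 0):
        raise ValueError(f"initial state has negative components: {y0.tolist()}")
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    p = params.to_array(phi=phi)
    fl = 0.0 if floor is None else float(floor)
    status, t, y, rec_t, rec_y = _step_core(
        p, y0, 0.0, float(t_end), fl, float(rtol), float(atol),
        float(conv_tol), float(rec_dt), np.inf,
    )
    if status in (_STATUS_NONFINITE, _STATUS_UNDERFLOW, _STATUS_MAXSTEPS):
        raise IntegrationError(
            f"integration failed (status={status}) at t={t:.6g}, "
            f"state={y.tolist()}, phi={p[-1]}"
        )
    return status, t, y, rec_t, rec_y


def integrate(params: ModelParams, init: EcoState | np.ndarray,
              t_end: float = 1000.0, *, phi: float | None = None,
              floor: float | None = DEFAULT_FLOOR, rtol: float = 1e-8,
              atol: float = 1e-10, sample_dt: float = 1.0,
              stop_at_fixed_point: bool = False,
              conv_tol: float = 1e-10) -> Trajectory:
    """Integrate the model for `t_end` time units and return a Trajectory.

    Parameters
    ----------
    floor
        Minimum level of B1, B2 and P, applied after every accepted step;
        None disables it.
    sample_dt
        Output sampling interval (linear interpolation on accepted steps).
    stop_at_fixed_point
        If True, stop once the off-floor residual ||dy/dt|| drops below
        `conv_tol` (the trajectory then ends early, at the fixed point).
    """
    status, t, y, rec_t, rec_y = _run(
        params, init if not isinstance(init, EcoState) else init.to_array(),
        t_end, phi, floor, rtol, atol,
        conv_tol if stop_at_fixed_point else 0.0, sample_dt,
    )
    # always include the endpoint actually reached
    if len(rec_t) == 0 or rec_t[-1] < t - 1e-9:
        rec_t = np.append(rec_t, t)
        rec_y = np.vstack([rec_y, y])
    return Trajectory(times=rec_t, states=rec_y, params=params, floor=floor)


def relax(params: ModelParams, phi: float, init: EcoState | np.ndarray,
          t_relax: float = 1000.0, *, floor: float | None = DEFAULT_FLOOR,
          rtol: float = 1e-8, atol: float = 1e-10,
          conv_tol: float = 1e-10) -> EcoState:
    """Endpoint of a `t_relax` integration at supply rate `phi`.

    Used by the sweep and pulse protocols; stops early once a fixed point
    is reached (which leaves the endpoint unchanged).
    """
    arr = init.to_array() if isinstance(init, EcoState) else init
    _, _, y, _, _ = _run(params, arr, t_relax, phi, floor, rtol, atol,
                         conv_tol, 0.0)
    return EcoState.from_array(y)


def residual(state: EcoState | np.ndarray, params: ModelParams, phi: float,
             floor: float | None = DEFAULT_FLOOR) -> float:
    """Max |dy/dt| ignoring components held at the floor (convergence metric)."""
    from .model_core import rhs

    y = np.asarray(state, dtype=np.float64)
    f = rhs(y, params, phi=phi)
    worst = abs(f[0])
    for j in range(1, 4):
        if floor is not None and y[j] <= floor * 1.0000001 and f[j] < 0:
            continue
        worst = max(worst, abs(f[j]))
    return float(worst)


def classify(final: EcoState | np.ndarray, params: ModelParams, phi: float,
             *, floor: float | None = DEFAULT_FLOOR,
             rel_tol: float = 0.05) -> RegimeLabel:
    """Match a converged state against the analytic steady states at `phi`.

    The label of the closest analytic state (relative L-infinity distance)
    is returned when that distance is below `rel_tol`, else OTHER. Species
    held at (or within a factor 2 of) the floor count as absent; 0.05 is
    far below the contrast between the alternative states yet generous to
    integrator residue. Near a fold the saddle approaches a stable state
    to within the tolerance; a converged endpoint is then credited to the
    stable state, so stable candidates win ties.
    """
    y = np.asarray(final, dtype=np.float64).copy()
    absent = 2.0 * floor if floor else 1e-8
    for j in (1, 2, 3):
        if y[j] <= absent:
            y[j] = 0.0
    best_stable: tuple[float, RegimeLabel] | None = None
    best_any: tuple[float, RegimeLabel] | None = None
    for rep in analytic.steady_states(params, phi):
        r = rep.state.to_array()
        dist = 0.0
        for j in range(4):
            if r[j] > absent:
                dist = max(dist, abs(y[j] - r[j]) / r[j])
            elif y[j] > absent:
                dist = math.inf
        if best_any is None or dist < best_any[0]:
            best_any = (dist, rep.label)
        if rep.stable and (best_stable is None or dist < best_stable[0]):
            best_stable = (dist, rep.label)
    if best_stable is not None and best_stable[0] < rel_tol:
        return best_stable[1]
    if best_any is not None and best_any[0] < rel_tol:
        return best_any[1]
    return RegimeLabel.OTHER
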