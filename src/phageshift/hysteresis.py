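"""Quasi-static hysteresis sweeps of the nutrient supply rate.

Protocol: starting from a near-empty environment, step phi along a grid
(default increment 0.01); at each grid point integrate the deterministic
model for t_relax = 1,000 time units with the species floor on, warm
starting from the endpoint of the previous grid point. On the way up the
B1-dominated branch persists until the upper threshold phi1, where the
ecosystem jumps discontinuously to the B2-dominated branch; on the way
down that branch survives to the lower threshold phi2 — the two jump
locations bracket the bistable window and form the hysteresis loop.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .model_core import EcoState, ModelParams, RegimeLabel
from .deterministic import DEFAULT_FLOOR, classify, relax, residual

__all__ = ["SweepResult", "HysteresisResult", "sweep", "hysteresis_loop"]


@dataclasses.dataclass
class SweepResult:
    """One branch of a quasi-static phi sweep."""

    direction: str  # 'up' | 'down'
    phi_values: np.ndarray
    branch_states: np.ndarray  # (n, 4)
    labels: list[RegimeLabel]
    jump_phi: list[float]  # midpoints of grid intervals where the label changes
    converged: np.ndarray  # off-floor residual < threshold at each grid point

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "phi": self.phi_values,
            "C": self.branch_states[:, 0],
            "B1": self.branch_states[:, 1],
            "B2": self.branch_states[:, 2],
            "P": self.branch_states[:, 3],
            "label": [str(l) for l in self.labels],
            "converged": self.converged,
        })

    def jumps_between(self, a: RegimeLabel, b: RegimeLabel) -> list[float]:
        """Jump midpoints where the label changes from `a` to `b`."""
        out = []
        for i in range(1, len(self.phi_values)):
            if self.labels[i - 1] is a and self.labels[i] is b:
                out.append(0.5 * (self.phi_values[i - 1] + self.phi_values[i]))
        return out


@dataclasses.dataclass
class HysteresisResult:
    up: SweepResult
    down: SweepResult
    bistable_interval: tuple[float, float] | None  # (down-jump, up-jump)


def _phi_grid(phi_start: float, phi_stop: float, dphi: float) -> np.ndarray:
    n = int(round(abs(phi_stop - phi_start) / dphi))
    sign = 1.0 if phi_stop >= phi_start else -1.0
    return np.round(phi_start + sign * dphi * np.arange(n + 1), 10)


def sweep(params: ModelParams, phi_start: float, phi_stop: float,
          dphi: float = 0.01, t_relax: float = 1000.0, *,
          floor: float = DEFAULT_FLOOR, init: EcoState | None = None,
          residual_tol: float = 1e-4, max_extensions: int = 3) -> SweepResult:
    """Warm-started quasi-static sweep from phi_start to phi_stop.

    The first grid point initialises at (C = phi/deltaC, floor, floor,
    floor) unless `init` is given; every later point starts from the
    previous endpoint. Grid points still mid-transient after t_relax
    (label OTHER or off-floor residual above `residual_tol` — critical
    slowing down near a jump) are relaxed for up to `max_extensions`
    further t_relax periods; endpoints still unconverged after that are
    flagged, not fatal.
    """
    if dphi <= 0 or t_relax <= 0:
        raise ValueError("dphi and t_relax must be > 0")
    phis = _phi_grid(phi_start, phi_stop, dphi)
    states = np.empty((len(phis), 4))
    labels: list[RegimeLabel] = []
    conv = np.empty(len(phis), dtype=bool)
    if init is None:
        state = EcoState(phi_start / params.deltaC if params.deltaC > 0 else 0.0,
                         floor, floor, floor)
    else:
        state = init
    for i, phi in enumerate(phis):
        state = relax(params, float(phi), state, t_relax, floor=floor)
        label = classify(state, params, float(phi), floor=floor)
        res = residual(state, params, float(phi), floor=floor)
        for _ in range(max_extensions):
            if label is not RegimeLabel.OTHER and res < residual_tol:
                break
            state = relax(params, float(phi), state, t_relax, floor=floor)
            label = classify(state, params, float(phi), floor=floor)
            res = residual(state, params, float(phi), floor=floor)
        states[i] = state.to_array()
        labels.append(label)
        conv[i] = res < residual_tol
    jumps = [0.5 * (phis[i - 1] + phis[i])
             for i in range(1, len(phis)) if labels[i] is not labels[i - 1]]
    direction = "up" if phi_stop >= phi_start else "down"
    return SweepResult(direction, phis, states, labels, jumps, conv)


def hysteresis_loop(params: ModelParams, phi_max: float = 1.0,
                    dphi: float = 0.01, t_relax: float = 1000.0, *,
                    phi_min: float = 0.0,
                    floor: float = DEFAULT_FLOOR) -> HysteresisResult:
    """Up-sweep phi_min→phi_max then down-sweep from the up-sweep endpoint.

    The bistable interval is (S→F down-jump, F→S up-jump) when both
    discontinuous transitions are found, None otherwise (no hysteresis).
    """
    up = sweep(params, phi_min, phi_max, dphi, t_relax, floor=floor)
    down = sweep(params, phi_max, phi_min, dphi, t_relax, floor=floor,
                 init=EcoState.from_array(up.branch_states[-1]))
    up_jumps = up.jumps_between(RegimeLabel.F, RegimeLabel.S)
    down_jumps = down.jumps_between(RegimeLabel.S, RegimeLabel.F)
    interval = None
    if up_jumps and down_jumps:
        interval = (down_jumps[0], up_jumps[0])
    return HysteresisResult(up=up, down=down, bistable_interval=interval)
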