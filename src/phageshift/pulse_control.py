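"""Impulsive control of the bistable ecosystem by population pulses.

A "population pulse" is a one-time instantaneous addition to one (or
several) of the four pools — phage P, nutrient C, or either bacterium —
applied to a stable state, followed by 1,000 time units of deterministic
relaxation with the species floor on. If the pulse pushes the system
across the basin boundary (the stable manifold of the unstable
coexistence saddle), the ecosystem undergoes the desired regime shift;
otherwise it falls back.

The grid scan reproduces the switching diagrams: for each supply rate on
a fine phi grid and each pulse magnitude (expressed by default as a
multiple of the pulsed variable's value in the *target* stable state),
the post-relaxation state is classified. Switching a B1-dominated
community to B2 dominance by P, C or B2 pulses works only above a lower
supply-rate bound; switching back by a B1 pulse works only below an
upper bound, and oversized B1 pulses can themselves fail (a reentrant
success region).
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .model_core import EcoState, ModelParams, RegimeLabel
from . import analytic
from .deterministic import DEFAULT_FLOOR, classify, relax

__all__ = [
    "PulseSpec",
    "PulseGrid",
    "PulseError",
    "TARGET_OF",
    "apply_pulse",
    "combined_pulse",
    "place_state",
    "scan",
    "switching_boundary",
    "bistable_phi_grid",
    "default_magnitudes",
]

_VAR_INDEX = {"C": 0, "B1": 1, "B2": 2, "P": 3}

#: which stable state a switching pulse aims for, per starting regime
TARGET_OF = {
    RegimeLabel.F: RegimeLabel.S,
    RegimeLabel.S: RegimeLabel.F,
    RegimeLabel.B1_ONLY: RegimeLabel.S,
    RegimeLabel.B2_ONLY: RegimeLabel.F,
}


class PulseError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class PulseSpec:
    """A single-variable instantaneous addition.

    magnitude is in raw model units (normalization='raw') or a multiple
    of the variable's value in the target stable state at the same phi
    (normalization='target', the convention of the switching diagrams).
    """

    variable: str
    magnitude: float
    normalization: str = "target"

    def __post_init__(self) -> None:
        if self.variable not in _VAR_INDEX:
            raise PulseError(f"variable must be one of {sorted(_VAR_INDEX)}")
        if self.magnitude < 0:
            raise PulseError("magnitude must be >= 0")
        if self.normalization not in ("raw", "target"):
            raise PulseError("normalization must be 'raw' or 'target'")


def _find_state(params: ModelParams, phi: float,
                label: RegimeLabel) -> EcoState:
    for rep in analytic.steady_states(params, phi):
        if rep.label is label:
            return rep.state
    raise PulseError(f"no {label.value} steady state exists at phi={phi}")


def _resolve_amount(pulse: PulseSpec, params: ModelParams, phi: float,
                    target: RegimeLabel) -> float:
    if pulse.normalization == "raw":
        return pulse.magnitude
    ref = _find_state(params, phi, target)
    return pulse.magnitude * ref.to_array()[_VAR_INDEX[pulse.variable]]


def combined_pulse(params: ModelParams, phi: float, start: RegimeLabel,
                   pulses: Sequence[PulseSpec], t_relax: float = 1000.0, *,
                   floor: float | None = DEFAULT_FLOOR) -> RegimeLabel:
    """Apply several pulses simultaneously to the `start` state, relax,
    classify. The phage-therapy scenario is a joint (P, B2) pulse on the
    B1-dominated state."""
    y = _find_state(params, phi, start).to_array()
    target = TARGET_OF.get(start)
    for pulse in pulses:
        if pulse.normalization == "target" and target is None:
            raise PulseError(f"no switching target defined for start={start}")
        y[_VAR_INDEX[pulse.variable]] += _resolve_amount(pulse, params, phi, target)
    final = relax(params, phi, y, t_relax, floor=floor)
    return classify(final, params, phi, floor=floor)


def apply_pulse(params: ModelParams, phi: float, start: RegimeLabel,
                pulse: PulseSpec, t_relax: float = 1000.0, *,
                floor: float | None = DEFAULT_FLOOR) -> RegimeLabel:
    """Single-variable pulse on the `start` state; returns the final label."""
    return combined_pulse(params, phi, start, [pulse], t_relax, floor=floor)


def place_state(params: ModelParams, phi: float, state: EcoState | np.ndarray,
                t_relax: float = 1000.0, *,
                floor: float | None = DEFAULT_FLOOR) -> RegimeLabel:
    """Set all four pools to `state` directly, relax and classify — the
    full-state control in which every variable is adjustable at once."""
    final = relax(params, phi, state, t_relax, floor=floor)
    return classify(final, params, phi, floor=floor)


@dataclasses.dataclass
class PulseGrid:
    """Outcomes of a (phi, magnitude) pulse scan from one starting regime."""

    phi_values: np.ndarray
    magnitudes: np.ndarray
    start_label: RegimeLabel
    target_label: RegimeLabel
    variable: str
    normalization: str
    outcome: np.ndarray  # (n_phi, n_mag) array of RegimeLabel

    @property
    def success(self) -> np.ndarray:
        """Boolean (n_phi, n_mag): pulse produced the target regime."""
        return np.vectorize(lambda l: l is self.target_label)(self.outcome)

    def to_dataframe(self) -> pd.DataFrame:
        phi, mag = np.meshgrid(self.phi_values, self.magnitudes, indexing="ij")
        return pd.DataFrame({
            "phi": phi.ravel(),
            "magnitude": mag.ravel(),
            "outcome": [str(l) for l in self.outcome.ravel()],
        })


def bistable_phi_grid(params: ModelParams, dphi: float = 0.01) -> np.ndarray:
    """Grid of multiples of dphi strictly inside the bistable window."""
    th = analytic.thresholds(params)
    if th.phi1 is None or th.phi2 is None:
        raise PulseError("no bistable window for these parameters")
    lo = math.floor(th.phi2 / dphi + 1.0) * dphi
    hi = (th.phi1 if math.isfinite(th.phi1) else 1.0) - dphi / 2
    n = int(math.floor((hi - lo) / dphi + 1e-9)) + 1
    return np.round(lo + dphi * np.arange(max(n, 0)), 10)


def default_magnitudes(n: int = 200, lo: float = 0.01,
                       hi: float = 3.0) -> np.ndarray:
    """Log-spaced pulse magnitudes (multiples of the target-state value)."""
    return np.geomspace(lo, hi, n)


def scan(params: ModelParams, start: RegimeLabel, variable: str,
         phi_values: np.ndarray | None = None,
         magnitudes: np.ndarray | None = None, *,
         normalization: str = "target", t_relax: float = 1000.0,
         floor: float | None = DEFAULT_FLOOR) -> PulseGrid:
    """Pulse `variable` on the `start` state over a (phi, magnitude) grid.

    Defaults: phi on a 0.01 grid across the bistable window, 200
    log-spaced magnitudes in [0.01, 3] x the target-state value.
    """
    if phi_values is None:
        phi_values = bistable_phi_grid(params)
    if magnitudes is None:
        magnitudes = default_magnitudes()
    phi_values = np.asarray(phi_values, dtype=np.float64)
    magnitudes = np.asarray(magnitudes, dtype=np.float64)
    if phi_values.size == 0 or magnitudes.size == 0:
        raise PulseError("phi and magnitude grids must be non-empty")
    target = TARGET_OF.get(start)
    if target is None:
        raise PulseError(f"no switching target defined for start={start}")
    idx = _VAR_INDEX[variable]
    outcome = np.empty((len(phi_values), len(magnitudes)), dtype=object)
    for i, phi in enumerate(phi_values):
        phi = float(phi)
        y0 = _find_state(params, phi, start).to_array()
        if normalization == "target":
            ref = _find_state(params, phi, target).to_array()[idx]
        else:
            ref = 1.0
        for j, mag in enumerate(magnitudes):
            y = y0.copy()
            y[idx] += float(mag) * ref
            final = relax(params, phi, y, t_relax, floor=floor)
            outcome[i, j] = classify(final, params, phi, floor=floor)
    return PulseGrid(phi_values, magnitudes, start, target, variable,
                     normalization, outcome)


def switching_boundary(grid: PulseGrid, which: str) -> float | None:
    """Largest ('max_phi') or smallest ('min_phi') phi whose magnitude
    column contains at least one successful switch; None when no cell
    switches anywhere. Resolution is one phi grid step."""
    if which not in ("min_phi", "max_phi"):
        raise ValueError("which must be 'min_phi' or 'max_phi'")
    cols = grid.success.any(axis=1)
    if not cols.any():
        return None
    phis = grid.phi_values[cols]
    return float(phis.max() if which == "max_phi" else phis.min())
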