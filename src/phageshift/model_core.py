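"""Dynamical core of the phage–bacterium chemostat model.

The model tracks a single limiting nutrient C, two bacterial species B1
(fast grower, phage-susceptible) and B2 (slow grower, partially resistant),
and one virulent phage P, all well mixed and supplied with nutrient at a
constant rate phi:

    dC/dt  = phi − deltaC·C − C·(lambda1·B1/Y1 + lambda2·B2/Y2)
    dB1/dt = B1·(lambda1·C − eta1·P − deltaB)
    dB2/dt = B2·(lambda2·C − eta2·P − deltaB)
    dP/dt  = P·(beta1·eta1·B1 + beta2·eta2·B2 − deltaP)

Growth is proportional to nutrient concentration (rate coefficient
lambda_i), consumption is growth divided by the yield Y_i, phage
infection follows mass action with adsorption coefficient eta_i and
burst size beta_i, and every pool is diluted or dies at a first-order
rate delta.

All quantities are in dimensionless model units; the state vector is
ordered (C, B1, B2, P) everywhere in the package, including file output.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import NamedTuple

import numpy as np

__all__ = [
    "ModelParams",
    "EcoState",
    "RegimeLabel",
    "fig1_defaults",
    "rhs",
    "jacobian",
    "PARAM_ORDER",
]

#: Flat ordering of the parameter vector used by the compiled kernels.
PARAM_ORDER = (
    "lambda1", "lambda2", "Y1", "Y2", "eta1", "eta2",
    "beta1", "beta2", "deltaC", "deltaB", "deltaP", "phi",
)


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """Rate and stoichiometry constants of the ecosystem.

    Defaults are the bistable reference parameter set used throughout the
    package: lambda1=1.0, lambda2=0.8, Y1=Y2=1, eta1=0.2, eta2=0.15,
    beta1=2, beta2=40, all deltas 0.2, phi=0.66.

    Parameters
    ----------
    lambda1, lambda2
        Growth-rate coefficients (per nutrient per time). lambda1 > lambda2
        makes B1 the fast grower.
    Y1, Y2
        Nutrient yields (biomass per nutrient); must be positive.
    eta1, eta2
        Phage adsorption coefficients (per phage per time).
    beta1, beta2
        Burst sizes (phage progeny per lysed cell). beta=0 with eta>0 is
        the perfect abortive-infection limit and is allowed.
    deltaC, deltaB, deltaP
        Dilution/death rates of nutrient, bacteria and phage (per time).
    phi
        Nutrient supply rate (nutrient per time).
    """

    lambda1: float = 1.0
    lambda2: float = 0.8
    Y1: float = 1.0
    Y2: float = 1.0
    eta1: float = 0.2
    eta2: float = 0.15
    beta1: float = 2.0
    beta2: float = 40.0
    deltaC: float = 0.2
    deltaB: float = 0.2
    deltaP: float = 0.2
    phi: float = 0.66

    def __post_init__(self) -> None:
        for name in PARAM_ORDER:
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")
        if self.Y1 <= 0 or self.Y2 <= 0:
            raise ValueError("yields Y1, Y2 must be > 0")

    def replace(self, **changes: float) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def with_phi(self, phi: float) -> "ModelParams":
        return self.replace(phi=phi)

    def to_array(self, phi: float | None = None) -> np.ndarray:
        """Flat float64 vector in :data:`PARAM_ORDER`, optionally overriding phi."""
        vec = np.array([getattr(self, name) for name in PARAM_ORDER], dtype=np.float64)
        if phi is not None:
            vec[-1] = phi
        return vec

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_ORDER}

    @classmethod
    def from_dict(cls, mapping: dict[str, float]) -> "ModelParams":
        unknown = set(mapping) - set(PARAM_ORDER)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})


def fig1_defaults() -> ModelParams:
    """The packaged bistable reference parameter set (phi = 0.66)."""
    return ModelParams()


class EcoState(NamedTuple):
    """One point (C, B1, B2, P) of phase space, all components >= 0."""

    C: float
    B1: float
    B2: float
    P: float

    def to_array(self) -> np.ndarray:
        return np.array(self, dtype=np.float64)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "EcoState":
        C, B1, B2, P = np.asarray(arr, dtype=np.float64)
        return cls(float(C), float(B1), float(B2), float(P))


class RegimeLabel(str, enum.Enum):
    """Qualitative ecosystem regimes.

    F is the B1-dominated state with phage present; S is the B2-dominated
    state with phage present. COEXISTENCE is the state where both bacteria
    are present at the isocline crossing (dynamically unstable under the
    bistability conditions, stable otherwise).
    """

    ABIOTIC = "ABIOTIC"
    B1_ONLY = "B1_ONLY"
    F = "F"
    S = "S"
    B2_ONLY = "B2_ONLY"
    COEXISTENCE = "COEXISTENCE"
    OTHER = "OTHER"

    def __str__(self) -> str:  # cleaner TSV output than 'RegimeLabel.F'
        return self.value


def _check_state(y: np.ndarray) -> None:
    if np.any(y < 0):
        raise ValueError(
            f"state has negative components {y.tolist()}; "
            "the model is defined on the non-negative orthant"
        )


def rhs(state: EcoState | np.ndarray, params: ModelParams,
        phi: float | None = None) -> np.ndarray:
    """Time derivative (dC/dt, dB1/dt, dB2/dt, dP/dt) at `state`.

    Raises ValueError on negative state components (integrator misuse).
    """
    y = np.asarray(state, dtype=np.float64)
    _check_state(y)
    p = params if phi is None else params.with_phi(phi)
    C, B1, B2, P = y
    dC = p.phi - p.deltaC * C - C * (p.lambda1 * B1 / p.Y1 + p.lambda2 * B2 / p.Y2)
    dB1 = B1 * (p.lambda1 * C - p.eta1 * P - p.deltaB)
    dB2 = B2 * (p.lambda2 * C - p.eta2 * P - p.deltaB)
    dP = P * (p.beta1 * p.eta1 * B1 + p.beta2 * p.eta2 * B2 - p.deltaP)
    return np.array([dC, dB1, dB2, dP])


def jacobian(state: EcoState | np.ndarray, params: ModelParams,
             phi: float | None = None) -> np.ndarray:
    """Analytic 4x4 Jacobian of :func:`rhs` with rows/columns (C, B1, B2, P)."""
    y = np.asarray(state, dtype=np.float64)
    _check_state(y)
    p = params if phi is None else params.with_phi(phi)
    C, B1, B2, P = y
    l1Y, l2Y = p.lambda1 / p.Y1, p.lambda2 / p.Y2
    return np.array([
        [-p.deltaC - l1Y * B1 - l2Y * B2, -l1Y * C, -l2Y * C, 0.0],
        [p.lambda1 * B1, p.lambda1 * C - p.eta1 * P - p.deltaB, 0.0, -p.eta1 * B1],
        [p.lambda2 * B2, 0.0, p.lambda2 * C - p.eta2 * P - p.deltaB, -p.eta2 * B2],
        [0.0, p.beta1 * p.eta1 * P, p.beta2 * p.eta2 * P,
         p.beta1 * p.eta1 * B1 + p.beta2 * p.eta2 * B2 - p.deltaP],
    ])
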