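"""Shared fixtures: the reference parameter set, random bistable
parameter sampling, and the expensive scan results (computed once per
session and reused by module and acceptance tests)."""

from __future__ import annotations

import numpy as np
import pytest

from phageshift import (
    ModelParams,
    RegimeLabel,
    bistability_conditions,
    fig1_defaults,
    hysteresis_loop,
    thresholds,
)
from phageshift import pulse_control as pc


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return fig1_defaults()


def sample_bistable_params(rng: np.random.Generator,
                           max_phi1: float = 2.0) -> ModelParams:
    """Draw a random parameter set satisfying the bistability orderings,
    with a bounded bistable window so sweeps stay desk-scale.

    Rates are drawn within a factor ~2 of the reference set: growth-rate
    ratio lambda2/lambda1 in (0.5, 0.95), adsorption ratio placed so B2
    is less susceptible per unit growth, and beta2 a few-fold above the
    stoichiometry threshold.
    """
    while True:
        lambda1 = rng.uniform(0.6, 1.6)
        lambda2 = lambda1 * rng.uniform(0.5, 0.95)
        eta1 = rng.uniform(0.12, 0.4)
        eta2 = eta1 * (lambda2 / lambda1) * rng.uniform(0.4, 0.9)
        Y1 = rng.uniform(0.7, 1.5)
        Y2 = rng.uniform(0.7, 1.5)
        beta1 = rng.uniform(1.0, 4.0)
        beta2_min = lambda2 * Y1 * beta1 * eta1 / (lambda1 * Y2 * eta2)
        beta2 = beta2_min * rng.uniform(3.0, 12.0)
        delta = rng.uniform(0.12, 0.3)
        p = ModelParams(lambda1=lambda1, lambda2=lambda2, Y1=Y1, Y2=Y2,
                        eta1=eta1, eta2=eta2, beta1=beta1, beta2=beta2,
                        deltaC=delta, deltaB=delta, deltaP=delta)
        if bistability_conditions(p).regime != "bistable":
            continue
        th = thresholds(p)
        if th.phi1 is None or th.phi2 is None:
            continue
        if not (0.05 < th.phi2 < th.phi1 < max_phi1):
            continue
        if th.phi1 - th.phi2 < 0.1:
            continue
        return p


@pytest.fixture(scope="session")
def hyst_loop(params):
    """Full quasi-static hysteresis loop, 0 -> 1 -> 0 at dphi = 0.01."""
    return hysteresis_loop(params, 1.0, 0.01, 1000.0)


@pytest.fixture(scope="session")
def b1_pulse_grid(params):
    """B1 pulses on the B2-dominated state: 200 magnitudes up to 2x the
    B1-dominated-state abundance, across the bistable window."""
    return pc.scan(params, RegimeLabel.S, "B1",
                   magnitudes=pc.default_magnitudes(200, 0.01, 2.0))


@pytest.fixture(scope="session")
def p_pulse_grid(params):
    """Phage pulses on the B1-dominated state: 200 magnitudes up to 3x
    the B2-dominated-state phage level, across the bistable window."""
    return pc.scan(params, RegimeLabel.F, "P",
                   magnitudes=pc.default_magnitudes(200, 0.01, 3.0))
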