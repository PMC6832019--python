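"""Closed-form steady states, thresholds and bistability classification."""

import math

import numpy as np
import pytest

from phageshift import (
    ModelParams,
    RegimeLabel,
    bistability_conditions,
    coexistence_point,
    hysteresis_jump_states,
    jacobian,
    phage_persistence_in_F,
    rhs,
    steady_states,
    thresholds,
)
from phageshift.analytic import (
    DegenerateGeometryError,
    NotBistableError,
    coexistence_abundances,
)

from conftest import sample_bistable_params


def _state(params, phi, label):
    for rep in steady_states(params, phi):
        if rep.label is label:
            return rep
    raise AssertionError(f"no {label} at phi={phi}")


class TestCoexistencePoint:
    def test_reference_set_crosses_at_1_4(self, params):
        cp = coexistence_point(params)
        assert (cp.C_star, cp.P_star) == (pytest.approx(1.0), pytest.approx(4.0))

    def test_hand_solved_system(self):
        # 1.2C - 0.3P = 0.2 and 0.9C - 0.1P = 0.2, eliminated by hand:
        # C = 4/15, P = 0.4
        p = ModelParams(lambda1=1.2, lambda2=0.9, eta1=0.3, eta2=0.1,
                        deltaB=0.2)
        cp = coexistence_point(p)
        assert cp.C_star == pytest.approx(4.0 / 15.0)
        assert cp.P_star == pytest.approx(0.4)

    def test_parallel_isoclines_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            coexistence_point(ModelParams(lambda1=1.0, lambda2=1.0,
                                          eta1=0.2, eta2=0.2))


class TestThresholds:
    def test_reference_values(self, params):
        th = thresholds(params)
        assert th.phi_B1 == pytest.approx(0.04)
        assert th.phi_P1 == pytest.approx(0.14)
        assert th.phi2 == pytest.approx(0.68 / 3)
        assert th.phi1 == pytest.approx(0.7)

    def test_abortive_infection_pushes_upper_bound_to_infinity(self, params):
        th = thresholds(params.replace(beta1=0.0))
        assert math.isinf(th.phi_P1) and math.isinf(th.phi1)
        assert th.phi2 == pytest.approx(0.68 / 3)

    def test_no_positive_coexistence_point_reported(self):
        # B2 more susceptible per growth: isoclines cross at negative P
        p = ModelParams(lambda1=1.0, lambda2=0.8, eta1=0.15, eta2=0.2)
        th = thresholds(p)
        assert th.phi1 is None and th.phi2 is None


class TestBistabilityConditions:
    def test_reference_set_bistable(self, params):
        rep = bistability_conditions(params)
        assert rep.regime == "bistable"
        th = thresholds(params)
        assert th.phi2 < th.phi1  # equivalent window formulation

    def test_small_burst_size_gives_stable_coexistence(self, params):
        rep = bistability_conditions(params.replace(beta2=2.0))
        assert rep.regime == "stable_coexistence"
        assert not rep.stoichiometry_ordering

    def test_equal_growth_rates_neither(self, params):
        assert bistability_conditions(
            params.replace(lambda2=1.0)).regime == "neither"

    def test_zero_rates_never_divide(self):
        rep = bistability_conditions(ModelParams(beta1=0.0, eta2=0.0))
        assert rep.regime in ("bistable", "stable_coexistence", "neither")

    def test_window_equivalence_on_random_sets(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            p = ModelParams(
                lambda1=rng.uniform(0.5, 1.5), lambda2=rng.uniform(0.3, 1.4),
                eta1=rng.uniform(0.05, 0.4), eta2=rng.uniform(0.05, 0.4),
                beta1=rng.uniform(1, 10), beta2=rng.uniform(1, 50),
                Y1=rng.uniform(0.5, 2), Y2=rng.uniform(0.5, 2))
            rep = bistability_conditions(p)
            th = thresholds(p)
            if th.phi1 is None or not rep.growth_ordering or not rep.susceptibility_ordering:
                continue
            assert (rep.regime == "bistable") == (th.phi2 < th.phi1)


class TestPhagePersistence:
    def test_reference_set_keeps_phage_in_both_states(self, params):
        assert phage_persistence_in_F(params)

    def test_abortive_limit_fails(self, params):
        assert not phage_persistence_in_F(params.replace(beta1=0.0))

    def test_small_adsorption_product_fails(self, params):
        # beta1=0.5 puts the phage-entry threshold (0.44) inside the
        # bistable window (0.2267, 2.2): recompute both sides
        p = params.replace(beta1=0.5)
        th = thresholds(p)
        assert th.phi2 < th.phi_P1 < th.phi1
        assert not phage_persistence_in_F(p)


class TestSteadyStates:
    def test_reference_abundances_inside_window(self, params):
        for phi in (0.25, 0.45, 0.65):
            assert _state(params, phi, RegimeLabel.F).state.B1 == pytest.approx(0.5)
            assert _state(params, phi, RegimeLabel.S).state.B2 == pytest.approx(0.2 / 6)

    def test_reference_values_at_phi_025(self, params):
        F = _state(params, 0.25, RegimeLabel.F).state
        assert F.C == pytest.approx(0.357, abs=5e-4)
        assert F.P == pytest.approx(0.786, abs=5e-4)
        U = _state(params, 0.25, RegimeLabel.COEXISTENCE).state
        assert U.B1 == pytest.approx(0.0246, abs=5e-5)
        assert U.B2 == pytest.approx(0.0317, abs=5e-5)
        assert (U.C, U.P) == (pytest.approx(1.0), pytest.approx(4.0))

    def test_below_survival_threshold_only_abiotic(self, params):
        reps = steady_states(params, 0.02)
        assert [r.label for r in reps] == [RegimeLabel.ABIOTIC]
        assert reps[0].stable

    def test_all_states_are_equilibria(self, params):
        for phi in (0.02, 0.1, 0.25, 0.5, 0.9):
            for rep in steady_states(params, phi, include_invadable=True):
                assert np.max(np.abs(rhs(rep.state, params, phi=phi))) < 1e-10

    def test_stability_pattern_in_window(self, params):
        for phi in (0.25, 0.45, 0.65):
            assert _state(params, phi, RegimeLabel.F).stable
            assert _state(params, phi, RegimeLabel.S).stable
            U = _state(params, phi, RegimeLabel.COEXISTENCE)
            assert not U.stable and max(U.eigenvalues.real) > 0

    def test_saddle_abundances_interpolate_linearly(self, params):
        th = thresholds(params)
        b1_scale, b2_scale = 0.2 / 0.4, 0.2 / 6.0
        for phi in np.linspace(th.phi2 + 1e-6, th.phi1 - 1e-6, 7):
            ab = coexistence_abundances(params, float(phi))
            x = (phi - th.phi2) / (th.phi1 - th.phi2)
            assert ab[0] == pytest.approx(b1_scale * x, rel=1e-9)
            assert ab[1] == pytest.approx(b2_scale * (1 - x), rel=1e-9)
        assert coexistence_abundances(params, th.phi2 - 0.01) is None
        assert coexistence_abundances(params, th.phi1 + 0.01) is None

    def test_stable_coexistence_regime(self, params):
        # reversed stoichiometry ordering: window (0.7, 0.7333) of stable
        # two-species coexistence
        p = params.replace(beta2=2.0)
        th = thresholds(p)
        assert th.phi1 < th.phi2
        rep = _state(p, 0.71, RegimeLabel.COEXISTENCE)
        assert rep.stable
        assert rep.state.B1 > 0 and rep.state.B2 > 0
        # independent 2x2 solve of the phage/nutrient balance lines
        A = np.array([[p.beta1 * p.eta1, p.beta2 * p.eta2],
                      [p.lambda1 / p.Y1, p.lambda2 / p.Y2]])
        b = np.array([p.deltaP, 0.71 / 1.0 - p.deltaC])
        np.testing.assert_allclose([rep.state.B1, rep.state.B2],
                                   np.linalg.solve(A, b), rtol=1e-12)

    def test_random_bistable_sets_have_saddle_between_stable_states(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            p = sample_bistable_params(rng)
            th = thresholds(p)
            phi = 0.5 * (max(th.phi2, th.phi_P1) + th.phi1)
            F = _state(p, phi, RegimeLabel.F)
            S = _state(p, phi, RegimeLabel.S)
            U = _state(p, phi, RegimeLabel.COEXISTENCE)
            assert F.stable and S.stable
            assert max(U.eigenvalues.real) > 0
            for rep in (F, S, U):
                assert np.max(np.abs(rhs(rep.state, p, phi=phi))) < 1e-10


class TestCrossPoints:
    def test_reference_values(self, params):
        xp = hysteresis_jump_states(params)
        assert xp.C2x == pytest.approx(3.09, abs=5e-3)
        assert xp.P2x == pytest.approx(15.14, abs=5e-3)
        assert xp.C1x == pytest.approx(0.3238, abs=5e-5)
        assert xp.P1x == pytest.approx(0.6190, abs=5e-5)

    def test_upper_cross_is_S_state_at_phi1(self, params):
        th = thresholds(params)
        xp = hysteresis_jump_states(params)
        S = _state(params, th.phi1, RegimeLabel.S).state
        assert xp.C2x == pytest.approx(S.C, rel=1e-12)
        assert xp.P2x == pytest.approx(S.P, rel=1e-12)

    def test_requires_bistable_parameters(self, params):
        with pytest.raises(NotBistableError):
            hysteresis_jump_states(params.replace(beta2=2.0))
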