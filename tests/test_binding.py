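"""Equilibrium, overflow bookkeeping and noise-free isotherms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

import itcvar as iv
from itcvar.binding import mole_ratios, reaction_heats


def bisection_complex(M, L, Ka, n=1.0):
    """Independent root-finding oracle on the mass-action residual."""
    k = Ka * 1e-3  # 1/mM
    hi = min(n * M, L)
    if hi == 0:
        return 0.0
    f = lambda x: k * (n * M - x) * (L - x) - x
    if f(hi) >= 0:  # root at the boundary within tolerance
        return hi
    return brentq(f, 0.0, hi, xtol=1e-15, rtol=8.9e-16)


class TestEquilibriumComplex:
    def test_no_titrant_no_complex(self):
        assert iv.equilibrium_complex(1.0, 0.0, 1e5) == 0.0

    def test_tight_binding_limit(self):
        assert iv.equilibrium_complex(1.0, 0.5, 1e12) == pytest.approx(0.5, rel=1e-6)

    def test_moderate_binding_value(self):
        # frozen from the bisection oracle at (1 mM, 0.5 mM, 1e5 1/M)
        ml = iv.equilibrium_complex(1.0, 0.5, 1e5)
        assert ml == pytest.approx(0.49038, abs=1e-5)
        assert ml == pytest.approx(bisection_complex(1.0, 0.5, 1e5), abs=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            iv.equilibrium_complex(-1.0, 0.5, 1e5)
        with pytest.raises(ValueError):
            iv.equilibrium_complex(1.0, 0.5, 0.0)

    def test_quadratic_matches_bisection_on_random_triples(self):
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            M = 10 ** rng.uniform(-4, 2)
            L = 10 ** rng.uniform(-4, 2)
            Ka = 10 ** rng.uniform(2, 9)
            got = iv.equilibrium_complex(M, L, Ka)
            want = bisection_complex(M, L, Ka)
            assert abs(got - want) < 1e-10

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        M=st.floats(1e-6, 1e3),
        L=st.floats(0.0, 1e3),
        Ka=st.floats(1e-2, 1e12),
        n=st.floats(0.5, 3.0),
    )
    def test_complex_bounded_by_reactants(self, M, L, Ka, n):
        ml = iv.equilibrium_complex(M, L, Ka, n)
        assert 0.0 <= ml <= min(n * M, L) + 1e-12


class TestApplyInjection:
    def test_dilution_arithmetic(self):
        state = iv.CellState(M_tot=1.0, L_tot=0.0, ML=0.0)
        out = iv.apply_injection(state, v=10.0, C_syr=0.0, V_cell=943.0, Ka=1e5)
        assert out.M_tot == pytest.approx(1.0 * 943 / 953, rel=1e-12)
        assert out.L_tot == 0.0

    def test_tiny_volume_is_near_identity(self):
        state = iv.CellState(M_tot=1.0, L_tot=0.0, ML=0.0)
        out = iv.apply_injection(state, v=1e-9, C_syr=6.0, V_cell=943.0, Ka=1e5)
        assert out.M_tot == pytest.approx(1.0, rel=1e-9)
        assert out.L_tot == pytest.approx(0.0, abs=1e-11)

    def test_zero_volume_rejected(self):
        state = iv.CellState(M_tot=1.0, L_tot=0.0, ML=0.0)
        with pytest.raises(ValueError):
            iv.apply_injection(state, v=0.0, C_syr=6.0, V_cell=943.0, Ka=1e5)

    def test_mole_conservation_under_overflow(self):
        """Titrand moles follow the product of dilution factors exactly."""
        config = iv.TitrationConfig(
            C_cell=2.5, C_syr=15.0, injection_volumes=(4.0, 10.0, 16.0, 7.0, 10.0)
        )
        rxn = iv.ReactionParams(Ka=1e6)
        states = iv.titration_states(config, rxn)
        factor = 1.0
        for state, v in zip(states[1:], config.injection_volumes):
            factor *= config.V_cell / (config.V_cell + v)
            assert state.M_tot == pytest.approx(2.5 * factor, rel=1e-14)


class TestInjectionHeat:
    def test_zero_enthalpy_zero_heat(self):
        a = iv.CellState(1.0, 0.1, 0.05)
        b = iv.CellState(0.99, 0.2, 0.15)
        assert iv.injection_heat(a, b, dH=0.0, V_cell=943.0, v=10.0) == 0.0

    @pytest.mark.parametrize("v,expected", [(4.0, 800.0), (10.0, 2000.0), (16.0, 3200.0)])
    def test_saturated_heat_equals_delivered_titrant(self, v, expected):
        """|Q| -> |dH| * C_syr * v when every injected mole binds."""
        config = iv.TitrationConfig(C_syr=5.0, C_cell=5.0, injection_volumes=(v,))
        rxn = iv.ReactionParams(Ka=1e9, dH=-40.0)
        iso = iv.simulate_isotherm(config, rxn)
        assert abs(iso.Q[0]) == pytest.approx(expected, rel=1e-3)
        assert iso.Q[0] < 0  # exothermic sign preserved

    def test_tight_binding_heats_within_0p1_percent_before_saturation(self):
        config = iv.TitrationConfig(C_syr=5.0, C_cell=5.0, injection_volumes=(10.0,) * 20)
        rxn = iv.ReactionParams(Ka=1e9, dH=-40.0)
        iso = iv.simulate_isotherm(config, rxn)
        assert np.all(np.abs(np.abs(iso.Q) - 2000.0) < 0.001 * 2000.0)


class TestSimulateIsotherm:
    def test_vanishing_Ka_gives_vanishing_heats(self):
        config = iv.TitrationConfig()
        iso = iv.simulate_isotherm(config, iv.ReactionParams(Ka=1e-6))
        assert np.all(np.abs(iso.Q) < 1e-3)

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError):
            iv.TitrationConfig(injection_volumes=())

    def test_high_c_transition_at_mole_ratio_one(self):
        """c=1000 isotherm is sigmoidal with its steep drop near ratio 1."""
        config, rxn = iv.standard_comparison(1000)
        iso = iv.simulate_isotherm(config, rxn)
        drop = np.abs(np.diff(np.abs(iso.Q)))
        ratio_at_drop = iso.mole_ratio[1:][np.argmax(drop)]
        assert 0.85 < ratio_at_drop < 1.15
        # plateaus on both sides of the transition
        assert abs(iso.Q[0]) > 100 * abs(iso.Q[-1])

    def test_monotone_saturation(self):
        config, rxn = iv.standard_comparison(100)
        states = iv.titration_states(config, rxn)
        frac = [s.bound_fraction(rxn.n) for s in states]
        assert np.all(np.diff(frac) > -1e-12)

    def test_heat_ledger_against_brute_force_mole_accounting(self):
        """Total heat equals dH times complex formed, tracked plug by plug."""
        config = iv.TitrationConfig(
            C_cell=1.0, C_syr=6.0, injection_volumes=(10.0,) * 25
        )
        rxn = iv.ReactionParams(Ka=1e5, dH=-40.0)
        iso = iv.simulate_isotherm(config, rxn)

        # brute-force ledger: track absolute moles, including every
        # expelled overflow plug's share of complex
        Vc = config.V_cell
        nM = config.C_cell * Vc  # nmol
        nL = 0.0
        ML_conc = 0.0
        total_formed = 0.0  # nmol of complex formed, summed per injection
        for v in config.injection_volumes:
            Vtot = Vc + v
            M_conc = nM / Vtot
            L_conc = (nL + config.C_syr * v) / Vtot
            ML_new = iv.equilibrium_complex(M_conc, L_conc, rxn.Ka, rxn.n)
            total_formed += ML_new * Vtot - ML_conc * Vc
            # expel plug of volume v at mixed composition
            nM = M_conc * Vc
            nL = L_conc * Vc
            ML_conc = ML_new
        assert iso.Q.sum() == pytest.approx(rxn.dH * total_formed, rel=1e-12)

    def test_mole_ratio_definition(self):
        config = iv.TitrationConfig(
            C_cell=2.0, C_syr=12.0, injection_volumes=(5.0,) * 10
        )
        expected = np.cumsum(12.0 * 5.0 * np.ones(10)) / (2.0 * 943.0)
        np.testing.assert_allclose(mole_ratios(config), expected, rtol=1e-14)


def test_vectorized_heats_match_scalar_path():
    """reaction_heats (array core) agrees with apply_injection step by step."""
    config = iv.TitrationConfig(
        C_cell=1.0, C_syr=6.0, injection_volumes=(4.0, 10.0, 16.0, 10.0)
    )
    rxn = iv.ReactionParams(Ka=3e5, dH=-25.0)
    Q = reaction_heats(
        np.array(config.injection_volumes), config.C_syr, config.C_cell,
        config.V_cell, rxn.Ka, rxn.dH, rxn.n,
    )[0]
    states = iv.titration_states(config, rxn)
    for i, v in enumerate(config.injection_volumes):
        q = iv.injection_heat(states[i], states[i + 1], rxn.dH, config.V_cell, v)
        assert Q[i] == pytest.approx(q, rel=1e-12)
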