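"""Rate laws, right-hand side assembly, and core model invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtenergy.model_core import (CellState, ParameterSet, STATE_NAMES,
                                 equation_terms, fluxes, free_ribosomes,
                                 insertion_rate_Alu, insertion_rate_L1,
                                 reference_state, replication_energy_rate,
                                 rhs, transcription_rate, translation_rate)


class TestParameterSet:
    def test_defaults_reproduce_published_table(self, params):
        # spot-check representative constants of every unit class
        assert params.Ng == 3.08e9
        assert params.A0 == 1.31e10
        assert params.w_q == 4.64
        assert params.k_subL == 5e-6
        assert params.lambda_L == 0.37
        assert params.S_wt == 13243.0

    @pytest.mark.parametrize("field", ["A0", "tau", "NL", "theta_q", "lambda_a"])
    def test_nonpositive_values_rejected(self, field):
        with pytest.raises(ValueError, match=field):
            ParameterSet(**{field: 0.0})

    def test_unknown_update_rejected_by_name(self, params):
        with pytest.raises(KeyError, match="wL"):
            params.with_updates(wL=3.0)


class TestCellState:
    def test_negative_variable_rejected(self):
        with pytest.raises(ValueError, match="mL"):
            reference_state().with_updates(mL=-1.0)

    def test_array_round_trip(self, ref_state):
        assert CellState.from_array(ref_state.to_array()) == ref_state


class TestRateLaws:
    def test_transcription_rate_at_reference(self, params):
        # Q * w_q * a/(theta_q + a) at the reference ATP level
        rate = transcription_rate(params.Q, params.w_q, params.theta_q, 5.32e9)
        assert rate == pytest.approx(1.03e4, rel=2e-3)

    def test_transcription_zero_and_saturation(self, params):
        assert transcription_rate(1064, 1.0, 3.8e9, 0.0) == 0.0
        sat = transcription_rate(1064, 1.0, 3.8e9, 1e30)
        assert sat == pytest.approx(1064.0, rel=1e-12)

    def test_transcription_negative_argument_rejected(self):
        with pytest.raises(ValueError):
            transcription_rate(-1.0, 1.0, 1.0, 1.0)

    def test_free_ribosomes_subtraction_and_clamp(self):
        assert free_ribosomes(0.0, 0.0, 9.5e6) == 9.5e6
        assert free_ribosomes(2.61e6, 1.8e5, 9.5e6) == pytest.approx(6.71e6)
        assert free_ribosomes(9e6, 1e6, 9.5e6) == 0.0

    def test_translation_rate_balances_protein_turnover(self, params):
        # at stationarity hk protein production equals its degradation:
        # d_q * q* = 5.67e-4 * 3.20e9
        v = translation_rate(2.61e6, 5.32e9, 300.0, 431.0, 25900.0)
        assert v == pytest.approx(5.67e-4 * 3.20e9, rel=2e-3)

    def test_translation_zero_complexes(self):
        assert translation_rate(0.0, 5e9, 300.0, 431.0, 25900.0) == 0.0

    def test_translation_saturation_is_gamma_over_length(self):
        # L1 protein length NL/3 = 2000 aa -> 0.15/min per complex
        v = translation_rate(1e5, 1e30, 300.0, 2000.0, 25900.0)
        assert v == pytest.approx(0.15 * 1e5, rel=1e-12)

    def test_translation_zero_length_rejected(self):
        with pytest.raises(ValueError):
            translation_rate(1.0, 1.0, 300.0, 0.0, 25900.0)

    def test_insertion_L1_balances_element_turnover(self, params):
        # stationarity of the L1 count: v_intL = lambda_L * L*
        v = insertion_rate_L1(2.83e3, 2.78e7, 5.32e9, params)
        assert v == pytest.approx(0.37 * 1.07e3, rel=2e-2)

    def test_insertion_L1_vanishes_without_complex_or_orf1p(self, params):
        assert insertion_rate_L1(0.0, 2.78e7, 5.32e9, params) == 0.0
        assert insertion_rate_L1(2.83e3, 0.0, 5.32e9, params) == 0.0

    def test_insertion_Alu_balances_element_turnover(self, params):
        # stationarity of the Alu count: v_intS = lambda_S * S*
        v = insertion_rate_Alu(5.64e3, 5.32e9, params)
        assert v == pytest.approx(1.18 * 1.34e4, rel=2e-2)

    def test_insertion_Alu_linear_in_complex(self, params):
        v1 = insertion_rate_Alu(5.64e3, 5.32e9, params)
        v2 = insertion_rate_Alu(2 * 5.64e3, 5.32e9, params)
        assert v2 == pytest.approx(2 * v1, rel=1e-12)

    def test_replication_basal_cost(self, params):
        # without insertions: Nnt * Ng / tau
        v = replication_energy_rate(5.32e9, 0.0, 0.0, 0.0, params)
        assert v == pytest.approx(15 * 3.08e9 / 1320, rel=1e-12)

    def test_replication_with_reference_insertions(self, params):
        v = replication_energy_rate(5.32e9, 2.83e3, 2.78e7, 5.64e3, params)
        expected = 15 * (3.08e9 / 1320 + 6000 * 0.37 * 1.07e3 + 300 * 1.18 * 1.34e4)
        assert v == pytest.approx(expected, rel=2e-2)

    def test_replication_vanishes_for_long_cycle(self, params):
        p = params.with_updates(tau=1e30)
        assert replication_energy_rate(1e9, 0.0, 0.0, 0.0, p) == pytest.approx(0.0, abs=1e-12)


class TestFluxes:
    def test_substitution_and_unbinding_at_reference(self, params, ref_state):
        f = fluxes(ref_state, params)
        assert f.sub_fwd == pytest.approx(5e-8 * 1.22e8 * 2.83e3, rel=1e-6)
        assert f.unbind_q == pytest.approx(0.01 * 2.61e6, rel=1e-6)

    def test_all_zero_state_has_zero_fluxes(self, params):
        f = fluxes(np.zeros(12), params)
        for name in ("omega_q", "omega_L", "omega_S", "v_q", "v_L",
                     "v_intL", "v_intS", "bind_q", "bind_L", "sub_fwd",
                     "sub_rev", "deg_a", "deg_L", "deg_S"):
            assert getattr(f, name) == 0.0

    def test_fluxes_nonnegative_at_random_admissible_states(self, params, ref_state):
        rng = np.random.default_rng(42)
        base = ref_state.to_array()
        for _ in range(20):
            y = base * 10.0 ** rng.uniform(-2, 2, size=12)
            f = fluxes(y, params)
            for name, value in vars(f).items():
                assert value >= 0.0, name


class TestRhs:
    def test_near_stationarity_at_printed_reference(self, params, ref_state):
        """The printed reference values nearly annihilate each balance.

        The cL-coupled equations (cL, O1, bL) are excluded: the printed
        cL is inconsistent with its own flux balance (the solver gives
        ~1.08e5, not 1.8e5), a documented discrepancy.
        """
        terms = equation_terms(ref_state, params)
        d = rhs(ref_state, params)
        excluded = {STATE_NAMES.index(n) for n in ("cL", "O1", "bL")}
        for i in range(12):
            if i in excluded:
                continue
            gross = sum(abs(t) for t in terms[i])
            assert abs(d[i]) <= 0.05 * gross, STATE_NAMES[i]

    def test_energy_only_term_cancellation(self, params):
        # With a tiny housekeeping transcription rate and nothing else
        # populated, only influx, ATP decay and basal replication remain.
        p = params.with_updates(w_q=1e-30)
        y = np.zeros(12)
        y[0] = 2e9
        d = rhs(y, p)
        expected = p.A0 - p.lambda_a * 2e9 - p.Nnt * p.Ng / p.tau
        assert d[0] == pytest.approx(expected, rel=1e-12)
        assert np.allclose(d[1:], 0.0, atol=1e-20)

    def test_reduced_freezes_alu_variables(self, params, ref_state):
        y = ref_state.with_updates(mS=0.0, bS=0.0, S=0.0)
        d = rhs(y, params, reduced=True)
        for name in ("mS", "bS", "S"):
            assert d[STATE_NAMES.index(name)] == 0.0

    def test_reduced_removes_alu_fluxes_but_keeps_L1(self, params, ref_state):
        f = fluxes(ref_state, params, reduced=True)
        assert f.omega_S == f.v_intS == f.sub_fwd == f.sub_rev == 0.0
        assert f.omega_L > 0 and f.v_intL > 0

    def test_non_finite_state_rejected(self, params):
        y = np.zeros(12)
        y[3] = np.nan
        with pytest.raises(ValueError):
            rhs(y, params)

    def test_linearity_in_mrna_at_fixed_atp(self, params, ref_state):
        """Away from the ribosome clamp, rhs is affine in each species
        when ATP and the other variables are held fixed."""
        y = ref_state.to_array()
        i = STATE_NAMES.index("mq")
        d0, d1, d2 = (rhs(_with(y, i, s), params) for s in (1e6, 2e6, 3e6))
        assert np.allclose(d2 - d1, d1 - d0, rtol=1e-9, atol=1e-6)


def _with(y, i, value):
    z = y.copy()
    z[i] = value
    return z


@settings(max_examples=30, deadline=None)
@given(a=st.floats(min_value=0.0, max_value=1e12),
       a2=st.floats(min_value=0.0, max_value=1e12))
def test_michaelis_menten_factors_monotone_and_bounded(a, a2):
    """Every ATP saturation factor is monotone in a and bounded by 1."""
    p = ParameterSet()
    for K in (p.theta_q, p.K_gammaq, p.K_chiL):
        f = lambda x: x / (K + x) if x > 0 else 0.0
        assert 0.0 <= f(a) <= 1.0
        if a2 >= a:
            assert f(a2) >= f(a)


def test_atp_bookkeeping_conservation(params, ref_state):
    """A0 - da/dt equals the summed energy budget exactly (to 1e-12
    relative) at randomized admissible states."""
    from rtenergy.budget import energy_budget

    rng = np.random.default_rng(7)
    base = ref_state.to_array()
    for _ in range(30):
        y = base * 10.0 ** rng.uniform(-2, 2, size=12)
        state = CellState.from_array(y)
        consumption = params.A0 - rhs(state, params)[0]
        total = energy_budget(state, params).total()
        assert consumption == pytest.approx(total, rel=1e-12)


def test_decoupled_analytic_steady_state(params):
    """With all consumption channels effectively disabled, the ATP
    steady state is the closed form A0/lambda_a, and the integrated
    steady state matches to 1e-6 relative."""
    from rtenergy.steadystate import find_steady_state

    p = params.with_updates(w_q=1e-30, tau=1e30)
    init = CellState.from_array(np.zeros(12))
    ss = find_steady_state(p, init)
    expected = p.A0 / p.lambda_a
    assert expected == pytest.approx(1.31e10 / 1.47, rel=1e-12)
    assert ss.converged
    assert ss.state.a == pytest.approx(expected, rel=1e-6)


def test_finite_difference_jacobian_agreement(params, ref_ss):
    """Analytic Jacobian matches central finite differences at the
    reference state to 1e-5 relative."""
    from rtenergy.steadystate import jacobian

    y = ref_ss.state.to_array()
    J = jacobian(ref_ss.state, params)
    Jfd = np.zeros((12, 12))
    for j in range(12):
        h = 1e-6 * max(abs(y[j]), 1.0)
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] -= h
        Jfd[:, j] = (rhs(yp, params) - rhs(ym, params)) / (2 * h)
    scale = np.abs(J) + np.abs(Jfd)
    mask = scale > 1e-12 * scale.max()
    assert np.max(np.abs(J - Jfd)[mask] / scale[mask]) < 1e-5
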