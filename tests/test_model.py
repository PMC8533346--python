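"""Unit tests for the model right-hand side: rates, currents, kinetics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slowwave import model
from slowwave.model import C_SIGMOID
from slowwave.params import CouplingSpec, column_preset


@pytest.fixture(scope="module")
def nrem():
    return column_preset("nrem", 1)


class TestFiringRate:
    def test_half_activation_at_threshold(self, nrem):
        q = model.firing_rate(nrem.pyramidal.theta, nrem.pyramidal)
        assert q == pytest.approx(0.5 * nrem.pyramidal.Qmax)

    def test_limits(self, nrem):
        assert model.firing_rate(-1e6, nrem.pyramidal) == pytest.approx(0.0)
        assert model.firing_rate(1e6, nrem.pyramidal) == pytest.approx(
            nrem.pyramidal.Qmax)

    def test_matches_direct_formula_evaluation(self, nrem):
        # independent arithmetic evaluation of the sigmoid at V = -50 mV
        p = nrem.pyramidal
        expected = p.Qmax * (1 + math.tanh(
            (math.pi / (2 * math.sqrt(3))) * (-50.0 - p.theta) / p.sigma)) / 2
        assert expected == pytest.approx(0.0273, abs=5e-4)  # sanity anchor
        assert model.firing_rate(-50.0, p) == pytest.approx(expected,
                                                            rel=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(qmax=st.floats(0.001, 1.0), theta=st.floats(-70, -40),
           sigma=st.floats(1.0, 12.0))
    def test_bounded_and_monotone(self, qmax, theta, sigma):
        from slowwave.params import PopulationParams
        pop = PopulationParams(qmax, theta, sigma, 30.0, -66.0)
        v = np.linspace(-120.0, 20.0, 400)
        q = model.firing_rate(v, pop)
        assert np.all(q >= 0) and np.all(q <= qmax)
        assert np.all(np.diff(q) >= 0)
        near = np.abs(v - theta) < 3 * sigma  # strictly increasing off saturation
        assert np.all(np.diff(q[near]) > 0)


class TestCurrents:
    def test_leak_vanishes_at_reversal_and_is_linear(self, nrem):
        assert model.leak_current(nrem.pyramidal.E_L, nrem.pyramidal) == 0.0
        assert model.leak_current(-56.0, nrem.pyramidal) == pytest.approx(10.0)
        v = np.linspace(-100, 0, 7)
        assert np.all(np.sign(model.leak_current(v, nrem.pyramidal))
                      == np.sign(v - nrem.pyramidal.E_L))

    def test_synaptic_currents_vanish_at_reversal(self, nrem):
        st_ = model.ColumnState(Vp=0.0, Vi=0.0, Na=9.5, s_pp=1.0, s_ip=2.0,
                                s_pi=3.0, s_ii=4.0)
        ia_p, ia_i, _, _ = model.synaptic_currents(st_, nrem.synapses)
        assert ia_p == 0.0 and ia_i == 0.0
        st_ = model.ColumnState(Vp=-70.0, Vi=-70.0, Na=9.5, s_pi=1.0, s_ii=1.0)
        _, _, ig_p, ig_i = model.synaptic_currents(st_, nrem.synapses)
        assert ig_p == 0.0 and ig_i == 0.0

    def test_ampa_current_direct_value(self, nrem):
        syn = nrem.synapses.__class__(**{**nrem.synapses.__dict__})
        syn.g_AMPA_p = 2.0
        st_ = model.ColumnState(Vp=-60.0, Vi=-60.0, Na=9.5, s_pp=1.0)
        ia_p, _, _, _ = model.synaptic_currents(st_, syn)
        assert ia_p == pytest.approx(-120.0)

    def test_beta_zero_matches_one_column(self, nrem):
        coupled = model.ColumnState(Vp=-60.0, Vi=-55.0, Na=10.0, s_pp=1.0,
                                    s_ip=0.5, s_pi=2.0, s_ii=0.3,
                                    s_pp_inter=4.0, u_pp_inter=0.0,
                                    s_ip_inter=2.0, u_ip_inter=0.0)
        plain = model.ColumnState(Vp=-60.0, Vi=-55.0, Na=10.0, s_pp=1.0,
                                  s_ip=0.5, s_pi=2.0, s_ii=0.3)
        with_c = model.synaptic_currents(coupled, nrem.synapses,
                                         CouplingSpec(beta=0.0))
        without = model.synaptic_currents(plain, nrem.synapses)
        assert with_c == pytest.approx(without)

    def test_inter_activity_without_coupling_rejected(self, nrem):
        st_ = model.ColumnState(Vp=-60.0, Vi=-55.0, Na=10.0, s_pp_inter=1.0)
        with pytest.raises(ValueError, match="one-column"):
            model.synaptic_currents(st_, nrem.synapses)


class TestAdaptation:
    def test_half_activation_at_38_7(self, nrem):
        a = nrem.adaptation
        i = model.kna_current(-60.0, 38.7, a)
        assert i == pytest.approx(0.5 * 0.37 * a.g_KNa * (-60.0 - a.E_K))

    def test_reversal_and_saturation(self, nrem):
        a = nrem.adaptation
        assert model.kna_current(a.E_K, 20.0, a) == pytest.approx(0.0)
        sat = model.kna_current(-60.0, 1e9, a)
        assert sat == pytest.approx(0.37 * a.g_KNa * (-60.0 - a.E_K), rel=1e-6)
        na = np.linspace(1.0, 60.0, 50)
        assert np.all(np.diff(model.kna_current(-60.0, na, a)) > 0)

    def test_nonpositive_sodium_rejected(self, nrem):
        with pytest.raises(ValueError):
            model.kna_current(-60.0, 0.0, nrem.adaptation)
        with pytest.raises(ValueError):
            model.na_dynamics(-1.0, 0.01, nrem.adaptation)

    def test_resting_sodium_is_equilibrium(self, nrem):
        a = nrem.adaptation
        assert model.na_dynamics(a.Na_eq, 0.0, a) == pytest.approx(0.0)
        assert model.na_dynamics(a.Na_eq, 0.01, a) > 0

    def test_steady_sodium_matches_long_integration(self, nrem):
        # oracle: 1-D root on the influx/extrusion balance vs brute-force
        # integration of the scalar sodium ODE at constant firing
        from slowwave.integrate import heun_integrate
        a = nrem.adaptation
        qp = 0.02
        na_star = model.steady_sodium(qp, a)
        na_end = heun_integrate(
            lambda na: model.na_dynamics(na, qp, a),
            np.array([a.Na_eq]), dt=1.0, n_steps=20000)
        assert na_end[0] == pytest.approx(na_star, rel=1e-6)


class TestSynapseKinetics:
    @settings(max_examples=20, deadline=None)
    @given(n=st.floats(1.0, 200.0), q=st.floats(0.0, 0.06),
           mu=st.floats(0.0, 2.0), gamma=st.floats(0.01, 0.2))
    def test_steady_state_is_nq_plus_drive(self, n, q, mu, gamma):
        s_star = n * q + mu
        ds, du = model.synapse_rhs(s_star, 0.0, q, n, gamma, mu)
        assert ds == 0.0 and du == pytest.approx(0.0, abs=1e-12)

    def test_rest_stays_at_rest(self):
        assert model.synapse_rhs(0.0, 0.0, 0.0, 10.0, 0.07, 0.0) == (0.0, 0.0)

    def test_impulse_response_is_alpha_function(self):
        # oracle: closed-form alpha kernel gamma^2 t exp(-gamma t)
        from slowwave.integrate import heun_integrate
        gamma, dt, n = 0.07, 0.01, 20000
        def f(y):
            ds, du = model.synapse_rhs(y[0], y[1], 0.0, 0.0, gamma, 0.0)
            return np.array([ds, du])
        traj = heun_integrate(f, np.array([0.0, gamma ** 2]), dt, n,
                              record=True)
        t = np.arange(n + 1) * dt
        expected = gamma ** 2 * t * np.exp(-gamma * t)
        assert np.max(np.abs(traj[:, 0] - expected)) < 1e-5 * expected.max()


class TestFullRHS:
    def test_fixed_point_has_zero_derivative(self, nrem):
        y = model.fixed_point(nrem, columns=1)
        dy = model.full_rhs(y, nrem, columns=1)
        assert np.max(np.abs(dy)) < 1e-10

    def test_two_column_beta_zero_decouples(self, nrem):
        c = CouplingSpec(beta=0.0, N_pp_inter=0.0, N_ip_inter=0.0)
        rng = np.random.default_rng(0)
        y1 = model.initial_guess(nrem, columns=1, Vp=-58.0, Vi=-57.0)
        y1 += rng.normal(0, 0.01, y1.shape)
        y2 = np.zeros(model.state_size(2))
        y2[:11] = y1
        y2[15:26] = y1
        d1 = model.full_rhs(y1, nrem, columns=1)
        d2 = model.full_rhs(y2, nrem, c, columns=2)
        np.testing.assert_array_equal(d2[:11], d1)
        np.testing.assert_array_equal(d2[15:26], d1)

    def test_symmetric_states_give_symmetric_derivatives(self, nrem):
        c = CouplingSpec(beta=2.0)
        y1 = model.initial_guess(nrem, c, columns=2, Vp=-57.0, Vi=-56.0)
        d = model.full_rhs(y1, nrem, c, columns=2)
        np.testing.assert_allclose(d[:15], d[15:], rtol=0, atol=0)

    def test_nonfinite_state_rejected(self, nrem):
        y = model.initial_guess(nrem, columns=1)
        y[0] = np.nan
        with pytest.raises(FloatingPointError):
            model.full_rhs(y, nrem, columns=1)
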