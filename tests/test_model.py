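"""Core dynamics: activation, the three update rules, and simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stpnet import (
    NetworkParams, activation, population_average, simulate, step_mean_field,
    step_microscopic, step_stochastic,
)
from stpnet.model import activation_deriv, iterate_mean_field, uniform_weights
from stpnet.params import ParameterError
from stpnet.states import (
    EnsembleState, MicroState, StateError, check_macro_bounds,
    default_initial_state,
)
from stpnet.fixed_points import closure

from conftest import random_admissible_state


class TestActivation:
    def test_half_at_zero_input(self):
        assert activation(0.0, 0.8) == 0.5

    def test_oracle_value(self):
        # (1 + tanh(1.25)) / 2, high-precision scalar reference
        assert activation(1.0, 0.8) == pytest.approx(
            0.9241418199787564, abs=1e-15)

    def test_saturation(self):
        assert activation(1e3, 0.8) == pytest.approx(1.0, abs=1e-12)
        assert activation(-1e3, 0.8) == pytest.approx(0.0, abs=1e-12)

    @given(h=st.floats(-50, 50), T=st.floats(0.01, 10))
    @settings(max_examples=200, deadline=None)
    def test_symmetry_and_range(self, h, T):
        g = activation(h, T)
        assert 0.0 <= g <= 1.0
        assert activation(-h, T) == pytest.approx(1.0 - g, abs=1e-12)

    @given(h=st.floats(-2, 2), T=st.floats(0.5, 3))
    @settings(max_examples=100, deadline=None)
    def test_monotone_increasing(self, h, T):
        # away from float saturation of tanh
        assert activation(h + 1e-3, T) > activation(h, T)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ParameterError):
            activation(np.nan, 0.8)
        with pytest.raises(ParameterError):
            activation(0.0, -1.0)

    def test_derivative_at_zero_is_half_beta(self):
        assert activation_deriv(0.0, 0.8) == pytest.approx(0.625, abs=1e-15)


class TestParams:
    def test_invariants_enforced(self):
        for bad in (dict(tau_R_E=0.5), dict(T_I=0.0), dict(U_se_E=0.0),
                    dict(U_se_I=1.5), dict(N_E=0)):
            with pytest.raises(ParameterError):
                NetworkParams(**bad)

    def test_tau_F_from_ratio(self):
        p = NetworkParams.single("E", 2.0, -1.0, 2.5, tau_ratio=11.7)
        assert p.tau_F_E == pytest.approx(70.0 / 11.7, rel=1e-15)

    def test_single_constructor_routes_fields(self):
        p = NetworkParams.single("I", -10.0, 1.0, 12.5)
        assert (p.J_II, p.I_I, p.tau_a_I) == (-10.0, 1.0, 12.5)
        assert p.J_EI == p.J_IE == 0.0 and not p.coupled


class TestMacroMap:
    def test_decoupled_activity_is_g_of_I(self, params_E):
        omega = default_initial_state(params_E, perturbation=0.0)
        out = step_mean_field(omega, params_E)
        # A = 0 kills every coupling term, so m(t+1) = g[I] exactly
        assert out[0] == pytest.approx(activation(-1.0, 0.8), abs=1e-15)

    def test_direct_product_structure(self, params_E):
        """Zero cross-coupling: the E block evolves independently of I."""
        omega = default_initial_state(params_E)
        traj = iterate_mean_field(omega, params_E, 200, keep=True)
        other = omega.copy()
        other[1::2] = [0.9, 2.0, 0.3, 0.7]   # very different I-subnetwork
        traj2 = iterate_mean_field(other, params_E, 200, keep=True)
        np.testing.assert_allclose(traj[:, 0::2], traj2[:, 0::2], atol=1e-14)

    def test_bounds_invariant_under_iteration(self, rng):
        """m, X, U stay in [0,1] and A >= 0 from random admissible states."""
        params = NetworkParams.coupled_pair(
            E=(2.0, -1.0, 2.5), I=(-10.0, 16.0, 12.5), J_EI=-0.1, J_IE=3.0)
        omega = random_admissible_state(rng, n=100)
        for _ in range(10_000):
            omega = step_mean_field(omega, params)
        assert check_macro_bounds(omega, strict=False)

    def test_scalar_and_vector_paths_agree(self, params_E, rng):
        omega = random_admissible_state(rng)
        fast = iterate_mean_field(omega, params_E, 50, keep=True)
        slow = np.empty_like(fast)
        o = omega
        for t in range(50):
            o = step_mean_field(o, params_E)
            slow[t] = o
        np.testing.assert_allclose(fast, slow, atol=1e-12)

    def test_steady_state_closure(self):
        """Iterating the synapse updates at clamped activity reaches the
        algebraic stationary values."""
        p = NetworkParams.single("E", 0.0, 0.0, 2.5)
        m = 0.3
        A, X, U = 0.0, 1.0, p.U_se_E
        for _ in range(20_000):
            A = A - A / p.tau_a_E + m * X * U / p.U_se_E
            X = X + (1 - X) / p.tau_R_E - m * X * U
            U = U + (p.U_se_E - U) / p.tau_F_E + p.U_se_E * (1 - U) * m
        A_alg, X_alg, U_alg = closure(m, p.tau_a_E, p.tau_R_E,
                                      p.tau_F_E, p.U_se_E)
        assert abs(A - A_alg) < 1e-10
        assert abs(X - X_alg) < 1e-10
        assert abs(U - U_alg) < 1e-10


class TestStochastic:
    def test_silent_network_relaxes_to_rest(self):
        """With firing suppressed, a decays geometrically, x -> 1, u -> U_se."""
        p = NetworkParams.single("E", 0.0, -1e3, 2.5, N=50)
        rng = np.random.default_rng(0)
        st0 = EnsembleState.quiescent(p)
        st0.a_E[:] = 1.0
        st0.x_E[:] = 0.5
        st0.u_E[:] = 0.9
        st = st0
        for k in range(1, 4):
            st = step_stochastic(st, p, rng)
            np.testing.assert_allclose(
                st.a_E, 1.0 * (1 - 1 / p.tau_a_E) ** k, atol=1e-12)
        assert np.all(st.s_E == 0)
        for _ in range(2000):
            st = step_stochastic(st, p, rng)
        np.testing.assert_allclose(st.x_E, 1.0, atol=1e-6)
        np.testing.assert_allclose(st.u_E, p.U_se_E, atol=1e-6)

    def test_zero_temperature_threshold(self):
        p = NetworkParams.single("E", 0.0, 5.0, 2.5, N=200, T=1e-9)
        st = step_stochastic(EnsembleState.quiescent(p), p,
                             np.random.default_rng(0))
        assert np.all(st.s_E == 1.0)

    def test_clamped_field_firing_rate_matches_activation(self):
        """Monte-Carlo firing rate at constant input equals g[h]."""
        p = NetworkParams.single("E", 0.0, 0.7, 2.5, N=10_000)
        rng = np.random.default_rng(7)
        st = EnsembleState.quiescent(p)
        total, n_draws = 0.0, 0
        for _ in range(20):
            st = step_stochastic(st, p, rng)
            total += st.s_E.sum()
            n_draws += p.N_E
        rate = total / n_draws
        g = activation(0.7, 0.8)
        assert rate == pytest.approx(g, abs=4 * np.sqrt(g * (1 - g) / n_draws))

    def test_seed_reproducibility(self, params_E):
        t1 = simulate("stochastic", params_E.replace(N_E=200, N_I=200),
                      n_steps=50, transient=10, seed=42)
        t2 = simulate("stochastic", params_E.replace(N_E=200, N_I=200),
                      n_steps=50, transient=10, seed=42)
        np.testing.assert_array_equal(t1.data, t2.data)

    def test_permutation_equivariance(self, params_E):
        """Relabelling neurons commutes with the update under uniform
        weights: the synaptic field and the deterministic synapse
        updates are permutation-covariant (the spike draws then agree
        in distribution when the per-neuron variates are permuted too)."""
        from stpnet.model import _synaptic_field, _update_synapses
        p = params_E.replace(N_E=64, N_I=64)
        rng = np.random.default_rng(3)
        st = EnsembleState.quiescent(p)
        st.s_E[:] = rng.integers(0, 2, 64)
        st.a_E[:] = rng.uniform(0, 1, 64)
        st.x_E[:] = rng.uniform(0.5, 1, 64)
        st.u_E[:] = rng.uniform(0.1, 0.9, 64)
        perm = rng.permutation(64)
        stp = EnsembleState(st.s_E[perm], st.a_E[perm], st.x_E[perm],
                            st.u_E[perm], st.s_I, st.a_I, st.x_I, st.u_I)
        np.testing.assert_allclose(_synaptic_field(stp, p, "E"),
                                   _synaptic_field(st, p, "E")[perm],
                                   atol=1e-12)
        out = _update_synapses(st.s_E, st.a_E, st.x_E, st.u_E,
                               p.tau_a_E, p.tau_R_E, p.tau_F_E, p.U_se_E)
        outp = _update_synapses(stp.s_E, stp.a_E, stp.x_E, stp.u_E,
                                p.tau_a_E, p.tau_R_E, p.tau_F_E, p.U_se_E)
        for a, b in zip(out, outp):
            np.testing.assert_allclose(b, a[perm], atol=1e-15)

    def test_population_average_trivials(self, params_E):
        p = params_E.replace(N_E=4, N_I=2)
        st = EnsembleState(
            np.array([1.0, 1, 1, 1]), np.arange(4.0), np.ones(4),
            np.full(4, 0.1), np.array([0.0, 1.0]), np.zeros(2), np.ones(2),
            np.full(2, 0.1))
        avg = population_average(st)
        assert avg[0] == 1.0          # all E spiking
        assert avg[1] == 0.5          # half the I population
        assert avg[2] == pytest.approx(1.5)

    def test_empty_subnetwork_rejected(self):
        with pytest.raises(ParameterError):
            NetworkParams(N_E=0)


class TestMicroscopic:
    def test_full_uniform_weights_reproduce_macro_exactly(self, params_E):
        """Identical neurons + uniform weights including the self term
        collapse onto the macroscopic map."""
        p = params_E.replace(N_E=50, N_I=50)
        omega = default_initial_state(p)
        W = uniform_weights(p)
        W["EE"][np.diag_indices(50)] = p.J_EE / 50   # restore self term
        ms = MicroState(*(np.full(50, omega[i]) for i in (0, 2, 4, 6)),
                        *(np.full(50, omega[i]) for i in (1, 3, 5, 7)))
        om = omega
        for _ in range(300):
            ms = step_microscopic(ms, p, W)
            om = step_mean_field(om, p)
        np.testing.assert_allclose(ms.m_E, om[0], atol=1e-12)
        np.testing.assert_allclose(ms.A_E, om[2], atol=1e-12)

    def test_self_exclusion_is_order_one_over_n(self, params_E):
        """With the self term excluded the one-step deviation from the
        macroscopic map is O(1/N)."""
        p = params_E.replace(N_E=100, N_I=100)
        omega = default_initial_state(p)
        omega[2] = 1.0   # nonzero A so the recurrent term matters
        ms = MicroState(*(np.full(100, omega[i]) for i in (0, 2, 4, 6)),
                        *(np.full(100, omega[i]) for i in (1, 3, 5, 7)))
        out = step_microscopic(ms, p, uniform_weights(p))
        om = step_mean_field(omega, p)
        dev = abs(out.m_E.mean() - om[0])
        assert 0 < dev < 5.0 / 100

    def test_zero_weights_relax_to_g_of_I(self):
        p = NetworkParams.single("E", 0.0, 0.5, 2.5, N=3)
        W = {k: np.zeros_like(v) for k, v in uniform_weights(p).items()}
        ms = MicroState(*(np.full(3, 0.2) for _ in range(4)),
                        *(np.full(3, 0.2) for _ in range(4)))
        for _ in range(5):
            ms = step_microscopic(ms, p, W)
        np.testing.assert_allclose(ms.m_E, activation(0.5, 0.8), atol=1e-12)

    def test_dimension_mismatch_rejected(self, params_E):
        p = params_E.replace(N_E=4, N_I=4)
        ms = MicroState(*(np.zeros(4) for _ in range(8)))
        W = uniform_weights(p)
        W["EE"] = np.zeros((3, 3))
        with pytest.raises(ParameterError):
            step_microscopic(ms, p, W)


class TestSimulate:
    def test_transient_discard_and_length(self, params_E):
        t = simulate("macroscopic", params_E, n_steps=11, transient=10)
        assert len(t) == 1 and t.t0 == 10

    def test_fig6_excitatory_parameters_sustain_oscillation(self, presets):
        t = simulate("macroscopic", presets["fig6E"].params,
                     n_steps=12_000, transient=10_000)
        m = t.column("m0E")
        assert m.max() - m.min() > 0.1

    def test_invalid_step_counts(self, params_E):
        with pytest.raises(ValueError):
            simulate("macroscopic", params_E, n_steps=5, transient=5)
        with pytest.raises(ValueError):
            simulate("unknown", params_E, n_steps=5)

    def test_state_error_on_bad_trajectory(self):
        with pytest.raises(StateError):
            from stpnet.states import Trajectory
            Trajectory(np.zeros((3, 5)))
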