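"""Newton fixed points, the analytic Jacobian, and stability labels."""

import numpy as np
import pytest

from stpnet import NetworkParams, classify_stability, jacobian, \
    solve_fixed_points, step_mean_field
from stpnet.fixed_points import (
    closure, fixed_point_step_residual, jacobian_block, sort_eigenvalues,
    synaptic_drive, synaptic_drive_deriv,
)

from conftest import random_admissible_state


class TestFixedPoints:
    def test_uncoupled_root_is_g_of_I(self):
        p = NetworkParams.single("E", 0.0, -1.0, 2.5)
        roots = solve_fixed_points(p)
        assert len(roots) == 1
        # (1 + tanh(-1.25)) / 2, high-precision scalar reference
        assert roots[0].m[0] == pytest.approx(0.07585818002124345, abs=1e-12)

    def test_zero_activity_closure_limit(self):
        A, X, U = closure(0.0, 2.5, 70.0, 6.0, 0.1)
        assert (A, X, U) == (0.0, 1.0, 0.1)

    def test_drive_matches_algebraic_elimination(self, rng):
        """The closed-form stationary drive equals eliminating the
        stationary X and U explicitly, over random parameter draws."""
        for _ in range(100):
            m = rng.uniform(0, 1)
            tau_a = rng.uniform(1, 20)
            tau_R = rng.uniform(1, 150)
            tau_F = rng.uniform(1, 150)
            use = rng.uniform(0.01, 1.0)
            A, X, U = closure(m, tau_a, tau_R, tau_F, use)
            assert synaptic_drive(m, tau_a, tau_R, tau_F, use) == \
                pytest.approx(A, rel=1e-12)

    def test_drive_derivative_against_finite_difference(self, rng):
        for _ in range(20):
            m = rng.uniform(0.01, 0.99)
            args = (2.5, 70.0, 70 / 11.7, 0.1)
            h = 1e-7
            fd = (synaptic_drive(m + h, *args)
                  - synaptic_drive(m - h, *args)) / (2 * h)
            assert synaptic_drive_deriv(m, *args) == pytest.approx(fd, rel=1e-6)

    def test_fixed_point_invariant_under_map(self, params_E):
        for root in solve_fixed_points(params_E):
            assert root.residual <= 1e-12
            assert fixed_point_step_residual(root, params_E) <= 1e-10

    def test_multistart_deduplication(self, params_E):
        roots = solve_fixed_points(params_E, grid=15)
        ms = [r.m for r in roots]
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                assert np.hypot(ms[i][0] - ms[j][0],
                                ms[i][1] - ms[j][1]) >= 1e-6


class TestJacobian:
    def test_tau_a_diagonal_entry(self, params_E, rng):
        K = jacobian(random_admissible_state(rng), params_E)
        assert K[1, 1] == pytest.approx(1 - 1 / 2.5)   # E block
        assert K[5, 5] == pytest.approx(1 - 1 / 2.5)   # I block

    def test_structural_zeros(self, rng):
        """Entries the map's dependencies do not generate are exactly 0."""
        p = NetworkParams.coupled_pair(
            E=(2.0, -1.0, 2.5), I=(-10.0, 16.0, 12.5), J_EI=-0.1, J_IE=3.0)
        K = jacobian(random_admissible_state(rng), p)
        # m rows depend only on A columns
        for r in (0, 4):
            assert K[r, 0] == K[r, 2] == K[r, 3] == 0
            assert K[r, 4] == K[r, 6] == K[r, 7] == 0
        # synaptic rows never couple across subnetworks
        assert np.all(K[1:4, 4:] == 0)
        assert np.all(K[5:8, :4] == 0)

    def test_matches_finite_differences(self, rng):
        """Analytic K equals a central-difference Jacobian of the map."""
        p = NetworkParams.coupled_pair(
            E=(2.0, -1.0, 2.5), I=(-10.0, 16.0, 12.5), J_EI=-0.05, J_IE=2.0)
        from stpnet.fixed_points import BLOCKED_PERM
        h = 1e-6
        for _ in range(50):
            omega = random_admissible_state(rng)
            K = jacobian(omega, p)
            fd = np.empty((8, 8))
            for j in range(8):
                ep = omega.copy(); ep[j] += h
                em = omega.copy(); em[j] -= h
                fd[:, j] = (step_mean_field(ep, p)
                            - step_mean_field(em, p)) / (2 * h)
            fd_blocked = fd[np.ix_(BLOCKED_PERM, BLOCKED_PERM)]
            np.testing.assert_allclose(K, fd_blocked, atol=1e-6)

    def test_decoupled_spectrum_is_union_of_blocks(self, params_E, rng):
        omega = random_admissible_state(rng)
        K = jacobian(omega, params_E)
        full = np.sort_complex(np.linalg.eigvals(K))
        blocks = np.sort_complex(np.concatenate([
            np.linalg.eigvals(jacobian_block(K, "E")),
            np.linalg.eigvals(jacobian_block(K, "I"))]))
        np.testing.assert_allclose(full, blocks, atol=1e-10)


class TestStability:
    def test_all_inside_unit_circle_is_stable(self):
        label, lead = classify_stability(np.full(8, 0.9 + 0j))
        assert label == "stable" and lead == pytest.approx(0.9)

    def test_complex_pair_crossing_is_ns(self):
        ev = np.array([1.01 * np.exp(1j * 0.3), 1.01 * np.exp(-1j * 0.3),
                       0.5, 0.4, 0.3, 0.2, 0.1, 0.0])
        label, lead = classify_stability(ev)
        assert label == "NS-unstable" and lead == pytest.approx(1.01)

    def test_real_crossing_is_other(self):
        ev = np.array([1.2 + 0j, 0.5, 0.4, 0.3, 0.2, 0.1, 0.05, 0.0])
        assert classify_stability(ev)[0] == "other-unstable"

    def test_eigenvalue_ordering(self):
        ev = np.array([0.5 + 0.1j, 0.9, -0.9, 0.2])
        out = sort_eigenvalues(ev)
        assert out[0] == 0.9 and out[1] == -0.9   # tie broken by real part

    def test_ose_window_fixed_point_is_ns_unstable(self, params_E):
        """Inside the excitatory oscillation window the fixed point has
        lost stability through a complex pair."""
        root = solve_fixed_points(params_E)[0]
        K = jacobian_block(jacobian(root.omega, params_E), "E")
        label, lead = classify_stability(np.linalg.eigvals(K))
        assert label == "NS-unstable" and lead > 1
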