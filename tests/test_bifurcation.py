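"""Equilibrium branches, Jacobians, Hopf detection and criticality."""

import numpy as np
import pytest

from dbflip.bifurcation import (classify_amplitude_profile, equilibrium_branch,
                                equilibrium_state, equilibrium_u, find_hopf,
                                jacobian, jacobian_eigenvalues,
                                steady_activation_availability)
from dbflip.membrane import rhs_autonomous
from dbflip.params import GateParams, NeuronParams, four_state_na, three_state_na
from dbflip.presets import get_preset


def leak_only():
    return NeuronParams(c=70.0, g_l=5.0, v_l=-65.0, na=four_state_na(0.0),
                        gates=GateParams(), v_us=-60.0)


class TestEquilibria:
    def test_leak_only_branch_is_a_line_through_vl(self):
        p = leak_only()
        grid = np.linspace(-80, -50, 31)
        br = equilibrium_branch(p, grid)
        assert np.allclose(br.u, p.g_l * (grid - p.v_l))
        assert br.u[np.argmin(np.abs(grid - p.v_l))] == pytest.approx(0.0)

    def test_residual_below_tolerance_on_model_branch(self, fig8_branch):
        p = fig8_branch.params
        for i in range(0, fig8_branch.v.size, 200):
            res = rhs_autonomous(fig8_branch.states[i], fig8_branch.u[i],
                                 fig8_branch.s, p)
            assert np.max(np.abs(res)) <= 1e-8

    def test_fixed_point_has_zero_membrane_rhs(self):
        cp = get_preset("fig9_4state")
        y = equilibrium_state(cp.params, -50.0)
        u = equilibrium_u(cp.params, -50.0, s=cp.s)
        assert np.max(np.abs(rhs_autonomous(y, u, cp.s, cp.params))) < 1e-10


class TestJacobian:
    def test_leak_only_eigenvalue(self):
        # the voltage equation decouples: lambda = -g_L / C
        p = leak_only()
        y = equilibrium_state(p, p.v_l)
        ev = jacobian_eigenvalues(p, y, 0.0)
        assert np.min(np.abs(ev - (-p.g_l / p.c))) < 1e-9

    def test_central_difference_agrees_with_richer_stencil(self):
        """Oracle: 5-point finite-difference derivative."""
        cp = get_preset("fig8_3state")
        p = cp.params
        v = -50.0
        y = equilibrium_state(p, v)
        u = equilibrium_u(p, v, cp.s)
        j2 = jacobian(p, y, u, cp.s, h=1e-6)
        m = y.size
        j4 = np.empty((m, m))
        h = 1e-4
        for i in range(m):
            cols = []
            for step in (-2, -1, 1, 2):
                yy = y.copy()
                yy[i] += step * h
                cols.append(rhs_autonomous(yy, u, cp.s, p))
            j4[:, i] = (cols[0] - 8 * cols[1] + 8 * cols[2] - cols[3]) / (12 * h)
        scale = np.max(np.abs(j4))
        assert np.max(np.abs(j2 - j4)) / scale < 1e-6

    def test_stable_points_have_negative_real_parts(self, fig8_branch):
        idx = np.flatnonzero(fig8_branch.stable)[::150]
        for i in idx:
            assert fig8_branch.eigvals[i].real.max() < 0


class TestHopfDetection:
    def test_leak_only_has_no_hopf(self):
        br = equilibrium_branch(leak_only(), np.linspace(-80, -30, 201))
        assert find_hopf(br) == []

    def test_three_state_has_exactly_one_window(self, fig8_hopfs):
        assert len(fig8_hopfs) == 2

    def test_four_state_has_two_windows(self, fig9_hopfs):
        assert len(fig9_hopfs) == 4

    def test_hopf_points_are_refined_and_oscillatory(self, fig8_hopfs,
                                                     fig9_hopfs):
        from dbflip.bifurcation import _leading
        for name, hopfs in (("fig8_3state", fig8_hopfs),
                            ("fig9_4state", fig9_hopfs)):
            p = get_preset(name).params
            for h in hopfs:
                lam = _leading(p, h.v_star, h.s)
                assert abs(lam.real) <= 1e-8
                assert h.omega > 0

    def test_grid_convergence(self):
        cp = get_preset("fig8_3state")
        coarse = find_hopf(equilibrium_branch(
            cp.params, np.arange(-80.0, -10.0, 0.2), s=cp.s))
        fine = find_hopf(equilibrium_branch(
            cp.params, np.arange(-80.0, -10.0, 0.1), s=cp.s))
        assert len(coarse) == len(fine)
        for a, b in zip(coarse, fine):
            assert abs(a.u - b.u) / abs(b.u) < 0.005

    def test_db_gap_equilibria_are_stable_and_depolarized(self, fig9_branch,
                                                          fig9_hopfs):
        """Between the windows the only attractor is a depolarized stable
        state: the depolarization-block state."""
        u2, u3 = fig9_hopfs[1].u, fig9_hopfs[2].u
        gap = (fig9_branch.u > u2 + 0.05) & (fig9_branch.u < u3 - 0.05)
        assert gap.any()
        assert fig9_branch.stable[gap].all()
        assert fig9_branch.v[gap].min() > fig9_hopfs[0].v_star

    def test_three_state_shows_no_second_window_at_high_current(self):
        """Negative control for the flipping mechanism: the 3-state model
        stays silent over the full current range of the 4-state diagram."""
        cp = get_preset("fig8_3state")
        br = equilibrium_branch(cp.params, np.arange(-80.0, -10.0, 0.05),
                                s=cp.s)
        hs = find_hopf(br)
        assert len(hs) == 2
        assert max(h.u for h in hs) < 2.5   # nothing near the 3.2-4.1 window


class TestCriticalityRule:
    def test_normal_form_profiles(self):
        """Oracle: amplitudes measured on Hopf normal forms of known type.

        r' = mu r - r^3 has a stable cycle of amplitude 2*sqrt(mu)
        (peak-to-peak voltage analogue); r' = mu r + r^2 r - 0.02 r^5
        jumps to a finite-amplitude cycle at onset.
        """
        from scipy.integrate import solve_ivp

        def steady_amp(mu, sign_cubic, quintic=0.0):
            def f(t, z):
                x, y = z
                r2 = x * x + y * y
                gx = mu * x - y + sign_cubic * x * r2 - quintic * x * r2 ** 2
                gy = mu * y + x + sign_cubic * y * r2 - quintic * y * r2 ** 2
                return [gx, gy]
            sol = solve_ivp(f, (0, 2000), [0.5, 0.0], rtol=1e-9,
                            t_eval=np.linspace(1500, 2000, 2000))
            return 2 * np.sqrt(sol.y[0] ** 2 + sol.y[1] ** 2).max()

        deltas = (0.005, 0.02)
        sup = [steady_amp(d, -1.0) * 10 for d in deltas]   # mV-scaled
        sub = [steady_amp(d, +1.0, quintic=0.02) * 10 for d in deltas]
        assert classify_amplitude_profile(deltas, sup, big_amp=15.0) \
            == "supercritical"
        assert classify_amplitude_profile(deltas, sub, big_amp=15.0) \
            == "subcritical"

    def test_inconclusive_profile_is_flagged(self):
        assert classify_amplitude_profile((0.005, 0.02), [0.0, 0.0],
                                          big_amp=15.0) == "undetermined"


class TestOscillationWindowsOracle:
    def test_windows_bracket_hopf_points(self, fig8_hopfs, fig8_windows):
        u1, u2 = fig8_hopfs[0].u, fig8_hopfs[1].u
        grid, windows = fig8_windows
        du = grid[1] - grid[0]
        assert len(windows) == 1
        lo, hi = windows[0]
        # subcritical end may extend below the Hopf (cycle bistability)
        assert lo <= u1 + 1.5 * du
        assert abs(hi - u2) <= 1.5 * du


class TestActivationAvailability:
    def test_activation_normalized_and_availability_complete_at_rest(self):
        c = steady_activation_availability(four_state_na(1.0))
        assert c.activation.max() == pytest.approx(1.0)
        assert c.availability[0] == pytest.approx(1.0, abs=1e-3)

    def test_four_state_curves_are_hyperpolarized(self):
        """The 4-state model activates and inactivates at lower voltages
        than the 3-state reduction used in the bifurcation comparison."""
        c4 = steady_activation_availability(four_state_na(1.0, v_half_31=-42.0))
        c3 = steady_activation_availability(three_state_na(1.0, v_half_31=-42.0))
        d_act = c4.v_half_activation - c3.v_half_activation
        d_avail = c4.v_half_availability - c3.v_half_availability
        assert d_act < 0 and d_avail < 0
        assert (abs(d_act) + abs(d_avail)) / 2 == pytest.approx(5.0, abs=2.5)
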