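"""Equilibrium branches, linear stability and Hopf bifurcations.

Because every gate and the Markov occupancies relax to explicit functions
of voltage, the equilibrium manifold is parametrized by V* directly: at
each V* the kinetic variables take their clamped-voltage steady state and
the applied current follows in closed form from the current balance

    u(V*) = g_L (V* - V_L) + sum I_ion,ss(V*) + s (V* - V_us).

No numerical continuation is needed.  Stability comes from the Jacobian of
the conservation-reduced system; Hopf points are sign changes of the
leading eigenvalue's real part through a complex-conjugate pair, refined
by bisection in V.  Criticality is decided by simulation just past the
bifurcation: a small-amplitude cycle growing continuously (~sqrt growth)
marks a supercritical Hopf, an immediate finite-amplitude cycle a
subcritical one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .kinetics import (ChannelState, gate_steady_state_and_tau,
                       markov_stationary)
from .membrane import pack_state, rhs_autonomous
from .params import GATE_IDS, MarkovNaParams, NeuronParams

__all__ = [
    "EquilibriumBranch", "HopfPoint", "equilibrium_state", "equilibrium_u",
    "equilibrium_branch", "jacobian", "jacobian_eigenvalues", "find_hopf",
    "classify_hopf", "classify_amplitude_profile", "oscillation_windows",
    "steady_activation_availability", "ActivationCurves",
]

_IM_TOL = 1e-7       # below this, an eigenvalue counts as real
_RES_TOL = 1e-8      # max |rhs| accepted at an equilibrium


# ---------------------------------------------------------------------
# equilibria
# ---------------------------------------------------------------------

def equilibrium_state(p: NeuronParams, v: float) -> np.ndarray:
    """Full state with all kinetic variables at steady state for V = v."""
    return pack_state(v, ChannelState.at_rest(v, p.na, p.gates))


def equilibrium_u(p: NeuronParams, v: float, s: float = 0.0) -> float:
    """Applied current that balances the membrane at V* = v."""
    st = ChannelState.at_rest(v, p.na, p.gates)
    i_na = p.na.g_na_bar * st.x[0] * (v - p.na.v_na)
    dv_k = v - p.gates.v_k
    i_dr = p.gates.g_dr_bar * st.n * st.y_k * dv_k
    i_a = p.gates.g_a_bar * st.n_a ** 4 * st.l_a ** 3 * dv_k
    i_km = p.gates.g_km_bar * st.n_km ** 2 * st.l_km * dv_k
    return (p.g_l * (v - p.v_l) + i_na + i_dr + i_a + i_km
            + s * (v - p.v_us))


def jacobian(p: NeuronParams, y: np.ndarray, u: float, s: float = 0.0,
             h: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian of the reduced system at a state.

    The reduction (n_states - 1 occupancies) removes the zero eigenvalue
    of the redundant occupancy coordinate.
    """
    m = y.size
    jac = np.empty((m, m))
    for i in range(m):
        yp = y.copy()
        ym = y.copy()
        yp[i] += h
        ym[i] -= h
        jac[:, i] = (rhs_autonomous(yp, u, s, p)
                     - rhs_autonomous(ym, u, s, p)) / (2 * h)
    return jac


def jacobian_eigenvalues(p: NeuronParams, y: np.ndarray, u: float,
                         s: float = 0.0, *, check: bool = True) -> np.ndarray:
    """Eigenvalues (sorted by descending real part) at an equilibrium."""
    if check:
        res = np.max(np.abs(rhs_autonomous(y, u, s, p)))
        if res > 1e-6:
            raise ValueError(f"state is not an equilibrium (max|rhs|={res:.2e})")
    ev = np.linalg.eigvals(jacobian(p, y, u, s))
    return ev[np.argsort(-ev.real)]


@dataclass
class EquilibriumBranch:
    """Equilibrium curve sampled along V*, with stability information."""

    v: np.ndarray              # mV, strictly increasing
    u: np.ndarray              # balancing applied current
    s: float
    eigvals: np.ndarray        # shape (n_points, dim)
    stable: np.ndarray         # bool
    params: NeuronParams = None
    states: np.ndarray = None  # shape (n_points, dim)

    @property
    def leading_real(self) -> np.ndarray:
        return self.eigvals.real.max(axis=1)

    def to_frame(self) -> pd.DataFrame:
        lead = self.eigvals[np.arange(self.v.size),
                            np.argmax(self.eigvals.real, axis=1)]
        return pd.DataFrame({
            "V_star": self.v, "u": self.u,
            "re_lambda_max": lead.real, "im_lambda": np.abs(lead.imag),
            "stable": self.stable,
        })

    def plot(self, ax=None, **kw):
        import matplotlib.pyplot as plt
        ax = ax or plt.gca()
        st = self.stable
        ax.plot(self.u[st], self.v[st], ".", color="red",
                label="stable", **kw)
        ax.plot(self.u[~st], self.v[~st], ".", color="black",
                label="unstable", **kw)
        ax.set_xlabel("applied current u")
        ax.set_ylabel("V* (mV)")
        ax.legend()
        return ax


def equilibrium_branch(p: NeuronParams, v_grid, s: float = 0.0,
                       keep_states: bool = True) -> EquilibriumBranch:
    """Build the equilibrium branch over a voltage grid.

    Each point satisfies max|rhs| <= 1e-8 (in the model's scaled units) by
    construction; this is verified and enforced.
    """
    v_grid = np.asarray(v_grid, float)
    if np.any(np.diff(v_grid) <= 0):
        raise ValueError("v_grid must be strictly increasing")
    n_pts = v_grid.size
    dim = p.state_dim
    us = np.empty(n_pts)
    eigs = np.empty((n_pts, dim), complex)
    states = np.empty((n_pts, dim))
    for i, v in enumerate(v_grid):
        y = equilibrium_state(p, v)
        u = equilibrium_u(p, v, s)
        res = np.max(np.abs(rhs_autonomous(y, u, s, p)))
        if res > _RES_TOL:
            raise RuntimeError(f"equilibrium residual {res:.2e} at V={v}")
        us[i] = u
        eigs[i] = jacobian_eigenvalues(p, y, u, s, check=False)
        states[i] = y
    stable = eigs.real.max(axis=1) < 0
    return EquilibriumBranch(v=v_grid, u=us, s=s, eigvals=eigs,
                             stable=stable, params=p,
                             states=states if keep_states else None)


# ---------------------------------------------------------------------
# Hopf detection
# ---------------------------------------------------------------------

@dataclass
class HopfPoint:
    u: float                   # applied current at the bifurcation
    v_star: float              # mV
    omega: float               # rad/ms, imaginary part at the crossing
    s: float = 0.0
    criticality: str = "unclassified"
    #: +1 if the equilibrium is unstable for u > u_H, -1 otherwise
    unstable_side: int = 0


def _leading(p: NeuronParams, v: float, s: float):
    y = equilibrium_state(p, v)
    ev = jacobian_eigenvalues(p, y, equilibrium_u(p, v, s), s, check=False)
    return ev[0]


def find_hopf(branch: EquilibriumBranch) -> list:
    """All Hopf points along a branch, ordered by applied current.

    A Hopf is a sign change of the leading eigenvalue's real part carried
    by a complex-conjugate pair; collisions of a complex pair on the
    positive real axis (which change the eigenvalue's character but not
    the equilibrium's stability) are excluded by requiring a nonzero
    imaginary part at the refined crossing.
    """
    p, s = branch.params, branch.s
    lead_re = branch.leading_real
    lead_im = np.abs(branch.eigvals[np.arange(branch.v.size),
                                    np.argmax(branch.eigvals.real, axis=1)].imag)
    out = []
    for i in range(1, branch.v.size):
        if (lead_re[i - 1] < 0) == (lead_re[i] < 0):
            continue
        if max(lead_im[i - 1], lead_im[i]) <= _IM_TOL:
            continue  # real-eigenvalue crossing, not a Hopf
        v_h = brentq(lambda v: _leading(p, v, s).real,
                     branch.v[i - 1], branch.v[i], xtol=1e-10, rtol=1e-14)
        lam = _leading(p, v_h, s)
        omega = abs(lam.imag)
        if omega <= _IM_TOL:
            continue
        u_h = equilibrium_u(p, v_h, s)
        # which side of u_H is unstable?
        du = equilibrium_u(p, branch.v[i], s) - equilibrium_u(p, branch.v[i - 1], s)
        re_up = lead_re[i] if du > 0 else lead_re[i - 1]
        out.append(HopfPoint(u=float(u_h), v_star=float(v_h),
                             omega=float(omega), s=s,
                             unstable_side=+1 if re_up > 0 else -1))
    out.sort(key=lambda h: h.u)
    return out


# ---------------------------------------------------------------------
# criticality
# ---------------------------------------------------------------------

def classify_amplitude_profile(deltas, amps, big_amp: float,
                               growth_min: float = 1.2) -> str:
    """Decision rule on steady oscillation amplitudes just past a Hopf.

    ``amps[k]`` is the steady peak-to-peak amplitude at parameter distance
    ``deltas[k]`` into the unstable side (deltas increasing, and close to
    the bifurcation).  An immediate large amplitude marks a subcritical
    Hopf (finite jump onto a pre-existing cycle); small amplitudes growing
    with distance mark a supercritical one (continuous ~sqrt emergence).
    """
    amps = np.asarray(amps, float)
    if amps[0] >= big_amp:
        return "subcritical"
    if amps[-1] >= big_amp:
        # fold of cycles crossed between the probes: finite jump
        return "subcritical" if amps[0] > 0.1 * big_amp else "undetermined"
    if amps[0] > 0 and amps[-1] >= growth_min * amps[0]:
        return "supercritical"
    return "undetermined"


def _steady_amplitude(p: NeuronParams, u: float, s: float, y0: np.ndarray,
                      t_total: float, t_measure: float, rtol: float,
                      max_step: float) -> float:
    sol = solve_ivp(lambda t, y: rhs_autonomous(y, u, s, p),
                    (0.0, t_total), y0, method="LSODA", rtol=rtol,
                    atol=rtol * 1e-2, max_step=max_step,
                    t_eval=np.arange(t_total - t_measure, t_total, 0.05))
    if not sol.success:
        raise RuntimeError(f"criticality simulation failed at u={u}")
    v = sol.y[0]
    return float(v.max() - v.min())


def classify_hopf(p: NeuronParams, hopf: HopfPoint, *,
                  deltas=(0.005, 0.02), big_amp: float = 15.0,
                  kick_mv: float = 1.0, t_total: float = 4000.0,
                  t_measure: float = 1500.0, rtol: float = 1e-8,
                  max_step: float = 2.0) -> str:
    """Sub/supercritical label for a detected Hopf point, by simulation.

    The model is integrated at ``u = u_H + side * delta`` for increasing
    ``delta`` (scaled by max(1, |u_H|)), starting from the destabilized
    equilibrium plus a small voltage kick, and the steady peak-to-peak
    voltage amplitude is recorded; :func:`classify_amplitude_profile`
    turns the profile into a label.  Inconclusive profiles return
    ``"undetermined"`` rather than a guess.
    """
    if hopf.unstable_side == 0:
        raise ValueError("hopf point carries no unstable-side information")
    scale = max(1.0, abs(hopf.u))
    y0 = equilibrium_state(p, hopf.v_star)
    y0 = y0.copy()
    y0[0] += kick_mv
    amps = []
    for d in deltas:
        u = hopf.u + hopf.unstable_side * d * scale
        amps.append(_steady_amplitude(p, u, hopf.s, y0, t_total, t_measure,
                                      rtol, max_step))
    label = classify_amplitude_profile(np.asarray(deltas) * scale, amps,
                                       big_amp)
    hopf.criticality = label
    return label


# ---------------------------------------------------------------------
# simulation oracle: oscillation windows
# ---------------------------------------------------------------------

def oscillation_windows(p: NeuronParams, u_values, s: float = 0.0, *,
                        amp_threshold: float = 2.0, t_total: float = 1500.0,
                        t_measure: float = 600.0, kick_mv: float = 1.0,
                        rtol: float = 1e-8, max_step: float = 2.0,
                        v_window=(-80.0, -10.0)) -> list:
    """Contiguous u-intervals with sustained voltage oscillations.

    For each u the model is integrated from the (destabilized) equilibrium
    plus a small kick; the point is labelled oscillating when the
    peak-to-peak voltage in the measurement window exceeds
    ``amp_threshold`` (mV).  Serves as an independent simulation oracle
    for :func:`find_hopf`.
    """
    u_values = np.asarray(u_values, float)
    if u_values.size < 2:
        raise ValueError("need at least two u values")
    # map u -> equilibrium V* by inverting the closed-form u(V)
    vg = np.linspace(v_window[0], v_window[1], 2001)
    ug = np.array([equilibrium_u(p, v, s) for v in vg])
    osc = np.zeros(u_values.size, bool)
    for i, u in enumerate(u_values):
        j = int(np.argmin(np.abs(ug - u)))
        y0 = equilibrium_state(p, vg[j]).copy()
        y0[0] += kick_mv
        amp = _steady_amplitude(p, u, s, y0, t_total, t_measure, rtol,
                                max_step)
        osc[i] = amp > amp_threshold
    windows = []
    start = None
    for i, flag in enumerate(osc):
        if flag and start is None:
            start = u_values[i]
        if not flag and start is not None:
            windows.append((float(start), float(u_values[i - 1])))
            start = None
    if start is not None:
        windows.append((float(start), float(u_values[-1])))
    return windows


# ---------------------------------------------------------------------
# apparent activation / availability curves
# ---------------------------------------------------------------------

@dataclass
class ActivationCurves:
    v: np.ndarray
    activation: np.ndarray      # normalized stationary open occupancy
    availability: np.ndarray    # 1 - stationary inactivated occupancy
    v_half_activation: float | None
    v_half_availability: float | None


def steady_activation_availability(na: MarkovNaParams,
                                   v_grid=None) -> ActivationCurves:
    """Stationary activation and availability curves of a Na model.

    Activation is the stationary open-state occupancy normalized to its
    maximum over the grid; availability is one minus the stationary
    inactivated-state occupancy.  Half-voltages are located by linear
    interpolation of the first crossing of half maximum (flagged ``None``
    for flat curves).
    """
    if v_grid is None:
        v_grid = np.arange(-90.0, 0.0 + 1e-9, 0.1)
    v_grid = np.asarray(v_grid, float)
    xs = np.array([markov_stationary(v, na) for v in v_grid])
    act = xs[:, 0]
    if act.max() <= 0:
        raise ValueError("open-state occupancy vanishes on the whole grid")
    act = act / act.max()
    avail = 1.0 - xs[:, 1]
    avail_n = avail / avail.max()
    return ActivationCurves(
        v=v_grid, activation=act, availability=avail,
        v_half_activation=_first_half_crossing(v_grid, act),
        v_half_availability=_first_half_crossing(v_grid, avail_n),
    )


def _first_half_crossing(v, c, level: float = 0.5):
    for i in range(1, c.size):
        lo, hi = c[i - 1] - level, c[i] - level
        if lo == 0.0:
            return float(v[i - 1])
        if lo * hi < 0:
            frac = -lo / (hi - lo)
            return float(v[i - 1] + frac * (v[i] - v[i - 1]))
    return None
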