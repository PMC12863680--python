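"""Voltage-dependent channel kinetics.

Rate functions, gating steady states and time constants, Markov generator
matrices, stationary occupancies and instantaneous currents for the four
channel types (Markov Na, K-DR, K-A, K-M).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space

from .params import (GATE_IDS, GateParams, MarkovNaParams, RateParams,
                     SigmoidGate)

__all__ = [
    "eval_rate_f1", "eval_rate_f2", "eval_rate", "gate_steady_state_and_tau",
    "markov_rate_matrix", "markov_stationary", "channel_currents",
    "ChannelState",
]


def eval_rate_f1(v, p: RateParams):
    """Saturating sigmoid rate ``1 / (tau_min + exp(-(V - v_half)/k))``.

    Bounded by ``1/tau_min``; monotone in V with direction set by the sign
    of ``k`` (k > 0: rate grows with depolarization).
    """
    _check_v(v)
    with np.errstate(over="ignore"):   # saturates to 1/tau_min or 0
        return 1.0 / (p.tau_min
                      + np.exp(-(np.asarray(v, float) - p.v_half) / p.k))


def eval_rate_f2(v, p: RateParams):
    """Two-sided saturating rate, bounded in ``[1/tau_max, 1/tau_min]``.

    ``1 / (tau_min + 1 / (1/(tau_max - tau_min) + exp((V - v_half)/k)))``;
    for ``tau_max = inf`` this is identically :func:`eval_rate_f1`.
    """
    _check_v(v)
    if math.isinf(p.tau_max):
        return eval_rate_f1(v, p)
    v = np.asarray(v, float)
    with np.errstate(over="ignore"):   # saturates to the tau bounds
        inner = 1.0 / (p.tau_max - p.tau_min) + np.exp((v - p.v_half) / p.k)
        return 1.0 / (p.tau_min + 1.0 / inner)


def eval_rate(v, kind: str, p):
    if kind == "const":
        return p
    if kind == "f1":
        return eval_rate_f1(v, p)
    if kind == "f2":
        return eval_rate_f2(v, p)
    raise ValueError(f"unknown rate kind {kind!r}")


def gate_steady_state_and_tau(v, gate_id: str, gp: GateParams):
    """Steady state and time constant of one potassium-channel gate.

    ``gate_id`` is one of ``n, y_k, n_a, l_a, n_km, l_km``.  Gates of
    sigmoid type (``y_k``, ``l_km``) have voltage-independent time
    constants (300 ms and 1000 ms respectively).
    """
    _check_v(v)
    if gate_id not in GATE_IDS:
        raise ValueError(f"unknown gate {gate_id!r}; expected one of {GATE_IDS}")
    return getattr(gp, gate_id).steady_state_tau(np.asarray(v, float))


def markov_rate_matrix(v: float, p: MarkovNaParams) -> np.ndarray:
    """Generator matrix Q of the Markov Na chain at clamped voltage.

    ``Q[j-1, i-1]`` is the rate of transition i -> j, so occupancies evolve
    as ``dx/dt = Q x``; columns sum to zero (probability conservation).
    """
    _check_v(v)
    n = p.n_states
    q = np.zeros((n, n))
    for (i, j), (kind, val) in p.transitions.items():
        r = float(eval_rate(v, kind, val))
        q[j - 1, i - 1] += r
        q[i - 1, i - 1] -= r
    return q


def markov_stationary(v: float, p: MarkovNaParams) -> np.ndarray:
    """Stationary occupancy vector of the chain at clamped voltage.

    Computed from the null space of the generator; entries are
    non-negative and sum to one.
    """
    q = markov_rate_matrix(v, p)
    ns = null_space(q)
    if ns.shape[1] != 1:
        raise ValueError(f"degenerate generator at V={v} mV "
                         f"(null space dimension {ns.shape[1]})")
    x = ns[:, 0]
    x = x / x.sum()
    if np.any(x < -1e-9):
        raise ValueError(f"negative stationary occupancy at V={v} mV")
    x = np.clip(x, 0.0, None)
    return x / x.sum()


@dataclass
class ChannelState:
    """Occupancies of the Na chain plus the six K-gate variables."""

    x: np.ndarray        # length n_states, sums to 1
    n: float
    y_k: float
    n_a: float
    l_a: float
    n_km: float
    l_km: float

    def validate(self) -> None:
        if abs(self.x.sum() - 1.0) > 1e-9:
            raise ValueError("occupancies must sum to 1")
        vals = np.concatenate([self.x, [self.n, self.y_k, self.n_a,
                                        self.l_a, self.n_km, self.l_km]])
        if np.any(vals < -1e-12) or np.any(vals > 1 + 1e-12):
            raise ValueError("state variables must lie in [0, 1]")

    @classmethod
    def at_rest(cls, v: float, na: MarkovNaParams, gp: GateParams) -> "ChannelState":
        """All variables at their clamped-voltage steady state."""
        x = markov_stationary(v, na)
        ss = {g: gate_steady_state_and_tau(v, g, gp)[0] for g in GATE_IDS}
        return cls(x=x, **{k: float(v_) for k, v_ in ss.items()})


def channel_currents(v: float, st: ChannelState, p: MarkovNaParams,
                     gp: GateParams):
    """Instantaneous (I_Na, I_DR, I_A, I_KM) for the given state.

    Each is conductance x open fraction x driving force; I_Na uses the
    open-state occupancy ``x1``.
    """
    i_na = p.g_na_bar * st.x[0] * (v - p.v_na)
    dv_k = v - gp.v_k
    i_dr = gp.g_dr_bar * st.n * st.y_k * dv_k
    i_a = gp.g_a_bar * st.n_a ** 4 * st.l_a ** 3 * dv_k
    i_km = gp.g_km_bar * st.n_km ** 2 * st.l_km * dv_k
    return i_na, i_dr, i_a, i_km


def _check_v(v) -> None:
    if not np.all(np.isfinite(v)):
        raise ValueError("voltage must be finite")
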