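"""Single-compartment membrane model and step-protocol integration.

The membrane equation is

    C dV/dt = -g_L (V - V_L) - I_Na - I_DR - I_A - I_KM + u(t) - s(t)(V - V_us)

with the injected current modelled as in conductance-injection (dynamic
clamp) experiments: a voltage-independent component ``u`` plus a shunt of
conductance ``s`` referenced to ``V_us``.  ``u`` and ``s`` are piecewise
constant in time.

The state vector is ``[V, x_1 .. x_{n-1}, n, y_k, n_a, l_a, n_km, l_km]``;
the last Markov occupancy is recovered from conservation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetics import (ChannelState, eval_rate, gate_steady_state_and_tau,
                       markov_rate_matrix)
from .params import GATE_IDS, NeuronParams

__all__ = ["StepProtocol", "Trace", "applied_current", "rhs", "simulate",
           "rest_state", "step_response", "SAMPLE_DT"]

#: default sample interval, ms (20 kHz, the digitization rate of the
#: recordings the model emulates)
SAMPLE_DT = 0.05


def applied_current(v, u, s, v_us):
    """Injected current ``u - s (V - V_us)``."""
    return u - s * (v - v_us)


@dataclass(frozen=True)
class StepProtocol:
    """Contiguous piecewise-constant (u, s) schedule.

    ``segments`` is a sequence of ``(t_start, t_end, u, s)`` in ms and the
    model's current/conductance units.
    """

    segments: tuple

    def __post_init__(self) -> None:
        segs = tuple(tuple(map(float, s)) for s in self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("protocol must contain at least one segment")
        for (t0, t1, _, _) in segs:
            if not t1 > t0:
                raise ValueError("segment must have t_end > t_start")
        for a, b in zip(segs, segs[1:]):
            if abs(a[1] - b[0]) > 1e-9:
                raise ValueError("segments must be contiguous")

    @classmethod
    def single_step(cls, u: float, s: float = 0.0, duration: float = 500.0,
                    t0: float = 0.0) -> "StepProtocol":
        return cls(((t0, t0 + duration, u, s),))

    @classmethod
    def staircase(cls, u_values, s: float = 0.0,
                  step_ms: float = 500.0) -> "StepProtocol":
        segs, t = [], 0.0
        for u in u_values:
            segs.append((t, t + step_ms, float(u), s))
            t += step_ms
        return cls(tuple(segs))

    @property
    def t_start(self) -> float:
        return self.segments[0][0]

    @property
    def t_end(self) -> float:
        return self.segments[-1][1]

    def inputs_at(self, t: float):
        for (t0, t1, u, s) in self.segments:
            if t0 - 1e-9 <= t <= t1 + 1e-9:
                return u, s
        raise ValueError(f"t={t} ms outside protocol span "
                         f"[{self.t_start}, {self.t_end}]")


@dataclass
class Trace:
    """Uniformly sampled voltage trajectory with provenance metadata."""

    t: np.ndarray                 # ms, strictly increasing
    v: np.ndarray                 # mV
    protocol: StepProtocol | None = None
    states: np.ndarray | None = None   # full state trajectory, optional
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.v = np.asarray(self.v, float)
        if self.t.shape != self.v.shape:
            raise ValueError("t and v must have matching shapes")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    # -- plain-text round trip -----------------------------------------
    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        path = Path(path)
        df = pd.DataFrame({"time_ms": self.t, "V_mV": self.v})
        if self.states is not None:
            for i in range(self.states.shape[0]):
                df[f"state_{i}"] = self.states[i]
        df.to_csv(path, index=False)
        if sidecar:
            side = {"meta": self.meta}
            if self.protocol is not None:
                side["protocol"] = [list(s) for s in self.protocol.segments]
            path.with_suffix(".json").write_text(json.dumps(side, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trace":
        path = Path(path)
        df = pd.read_csv(path, float_precision="round_trip")
        proto, meta = None, {}
        side = path.with_suffix(".json")
        if side.exists():
            d = json.loads(side.read_text())
            meta = d.get("meta", {})
            if "protocol" in d:
                proto = StepProtocol(tuple(tuple(s) for s in d["protocol"]))
        state_cols = [c for c in df.columns if c.startswith("state_")]
        states = df[state_cols].to_numpy().T if state_cols else None
        return cls(df["time_ms"].to_numpy(), df["V_mV"].to_numpy(),
                   protocol=proto, states=states, meta=meta)


# ---------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------

def _gate_tables(p: NeuronParams):
    return [getattr(p.gates, g) for g in GATE_IDS]


def rhs(t: float, y: np.ndarray, proto: StepProtocol,
        p: NeuronParams) -> np.ndarray:
    """Time derivative of the full state under the protocol's inputs."""
    u, s = proto.inputs_at(t)
    return rhs_autonomous(y, u, s, p)


def rhs_autonomous(y: np.ndarray, u: float, s: float,
                   p: NeuronParams) -> np.ndarray:
    """Derivative at fixed (u, s); shared by simulation and equilibrium
    analysis."""
    n = p.n_states
    v = y[0]
    x = np.empty(n)
    x[: n - 1] = y[1:n]
    x[n - 1] = 1.0 - x[: n - 1].sum()
    g = y[n: n + 6]

    i_na = p.na.g_na_bar * x[0] * (v - p.na.v_na)
    dv_k = v - p.gates.v_k
    i_dr = p.gates.g_dr_bar * g[0] * g[1] * dv_k
    i_a = p.gates.g_a_bar * g[2] ** 4 * g[3] ** 3 * dv_k
    i_km = p.gates.g_km_bar * g[4] ** 2 * g[5] * dv_k

    dv = (-p.g_l * (v - p.v_l) - i_na - i_dr - i_a - i_km
          + applied_current(v, u, s, p.v_us)) / p.c

    q = markov_rate_matrix(v, p.na)
    dx = (q @ x)[: n - 1]

    dg = np.empty(6)
    for i, gate in enumerate(_gate_tables(p)):
        x_inf, tau = gate.steady_state_tau(v)
        dg[i] = (x_inf - g[i]) / tau

    out = np.empty(y.size)
    out[0] = dv
    out[1:n] = dx
    out[n:] = dg
    return out


def pack_state(v: float, st: ChannelState) -> np.ndarray:
    n = st.x.size
    return np.concatenate([[v], st.x[: n - 1],
                           [st.n, st.y_k, st.n_a, st.l_a, st.n_km, st.l_km]])


def unpack_state(y: np.ndarray, n_states: int):
    x = np.empty(n_states)
    x[: n_states - 1] = y[1:n_states]
    x[n_states - 1] = 1.0 - x[: n_states - 1].sum()
    g = y[n_states:]
    return y[0], ChannelState(x=x, n=g[0], y_k=g[1], n_a=g[2], l_a=g[3],
                              n_km=g[4], l_km=g[5])


# ---------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------

def steady_init(p: NeuronParams, v0: float = -70.0) -> np.ndarray:
    """Initial state with all kinetic variables at steady state for v0."""
    return pack_state(v0, ChannelState.at_rest(v0, p.na, p.gates))


def simulate(p: NeuronParams, proto: StepProtocol,
             init: np.ndarray | None = None, *, rtol: float = 1e-6,
             atol: float = 1e-8, sample_dt: float = SAMPLE_DT,
             max_step: float = 1.0, keep_states: bool = False) -> Trace:
    """Integrate the membrane ODE over a step protocol.

    A stiff-capable adaptive solver (LSODA) is restarted at each segment
    boundary so input discontinuities are sharp.  Output is sampled on a
    uniform grid (20 kHz equivalent by default).  Deterministic for
    identical inputs and tolerances.
    """
    if init is None:
        init = steady_init(p)
    y = np.asarray(init, float)
    if y.size != p.state_dim:
        raise ValueError(f"init has size {y.size}, expected {p.state_dim}")

    ts, ys = [], []
    for k, (t0, t1, u, s) in enumerate(proto.segments):
        n_samp = int(round((t1 - t0) / sample_dt))
        t_eval = t0 + sample_dt * np.arange(n_samp + (1 if k == len(proto.segments) - 1 else 0))
        sol = solve_ivp(
            lambda t, yy: rhs_autonomous(yy, u, s, p), (t0, t1), y,
            method="LSODA", rtol=rtol, atol=atol, max_step=max_step,
            t_eval=t_eval, dense_output=False)
        if not sol.success:
            raise RuntimeError(
                f"integration failed at t={sol.t[-1] if sol.t.size else t0} ms: "
                f"{sol.message}")
        # clamp tiny negative occupancy excursions
        occ = sol.y[1:p.n_states]
        occ[(occ < 0) & (occ > -1e-12)] = 0.0
        ts.append(sol.t)
        ys.append(sol.y)
        # advance with an exact segment-end state
        end = solve_ivp(lambda t, yy: rhs_autonomous(yy, u, s, p),
                        (sol.t[-1], t1), sol.y[:, -1], method="LSODA",
                        rtol=rtol, atol=atol, max_step=max_step)
        if not end.success:
            raise RuntimeError(f"integration failed at t={t1} ms: {end.message}")
        y = end.y[:, -1]

    t = np.concatenate(ts)
    ymat = np.concatenate(ys, axis=1)
    return Trace(t, ymat[0], protocol=proto,
                 states=ymat if keep_states else None,
                 meta={"preset": p.name, "rtol": rtol, "atol": atol})


def rest_state(p: NeuronParams, s: float = 0.0, settle_ms: float = 1000.0,
               v0: float = -70.0, rtol: float = 1e-8,
               atol: float = 1e-10) -> np.ndarray:
    """Resting state at u = 0 with the shunt conductance s engaged.

    Emulates the inter-step rest of a current-step protocol: the cell sits
    at its (possibly shunted) resting potential before each step.
    """
    sol = solve_ivp(lambda t, yy: rhs_autonomous(yy, 0.0, s, p),
                    (0.0, settle_ms), steady_init(p, v0), method="LSODA",
                    rtol=rtol, atol=atol, max_step=5.0)
    if not sol.success:
        raise RuntimeError(f"rest-state settling failed: {sol.message}")
    return sol.y[:, -1]


def step_response(p: NeuronParams, u: float, s: float = 0.0, *,
                  duration: float = 500.0, init: np.ndarray | None = None,
                  **kw) -> Trace:
    """Response to a single (u, s) step launched from rest.

    If ``init`` is not given, the resting state with the shunt engaged is
    computed first (each step of an experimental family starts from rest).
    """
    if init is None:
        init = rest_state(p, s)
    tr = simulate(p, StepProtocol.single_step(u, s, duration), init, **kw)
    tr.meta.update({"u": u, "s": s})
    return tr
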