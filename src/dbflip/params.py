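"""Parameter containers for the granule-cell model.

Two self-consistent unit dialects are supported and tagged on every
parameter set:

``point``
    whole-cell units: nS, pF, pA, mV, ms (currents in pA, ``I/C`` in mV/ms).
``density``
    membrane-density units: uS/cm2, uF/cm2, uA/cm2, mV, ms.

Both dialects satisfy ``dV/dt = I / C`` in mV/ms, so no internal conversion
is ever needed; the tag only documents the scale of ``u`` and the
conductances.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

RateKind = Literal["const", "f1", "f2"]
Dialect = Literal["point", "density"]

#: Markov state indices (1-based, as conventionally written):
#: 1 = open, 2 = inactivated, 3 = closed (high threshold), 4 = closed
#: (low threshold, 4-state model only).
OPEN, INACTIVATED, CLOSED_1, CLOSED_2 = 1, 2, 3, 4


@dataclass(frozen=True)
class RateParams:
    """Voltage-dependent transition-rate description.

    ``f1`` rates are ``1 / (tau_min + exp(-(V - v_half)/k))``; ``f2`` rates
    saturate at ``1/tau_max`` instead of falling to zero.  ``tau_max`` may be
    ``inf``, in which case ``f2`` reduces exactly to ``f1``.
    """

    tau_min: float            # ms
    v_half: float             # mV
    k: float                  # mV
    tau_max: float = math.inf  # ms

    def __post_init__(self) -> None:
        if not (self.tau_min > 0):
            raise ValueError("tau_min must be positive")
        if self.k == 0:
            raise ValueError("k must be nonzero")
        if not (self.tau_max > self.tau_min):
            raise ValueError("tau_max must exceed tau_min")


@dataclass(frozen=True)
class MarkovNaParams:
    """Markov sodium-channel model with 3 or 4 conformational states.

    ``transitions`` maps ``(i, j)`` (1-based state indices, transition
    i -> j) to either ``("const", rate)`` or ``("f1"|"f2", RateParams)``.
    """

    n_states: int
    transitions: dict
    g_na_bar: float           # nS or uS/cm2
    v_na: float = 65.0        # mV

    def __post_init__(self) -> None:
        if self.n_states not in (3, 4):
            raise ValueError("n_states must be 3 or 4")
        if self.g_na_bar < 0:
            raise ValueError("g_na_bar must be non-negative")
        for (i, j) in self.transitions:
            if not (1 <= i <= self.n_states and 1 <= j <= self.n_states):
                raise ValueError(f"transition ({i},{j}) out of range")
            if i == j:
                raise ValueError("self-transitions are not allowed")


def four_state_na(g_na_bar: float, v_na: float = 65.0, a12: float = 3.0,
                  v_half_31: float = -42.0) -> MarkovNaParams:
    """The 4-state sodium model: open (1), inactivated (2), two closed (3, 4).

    Defaults carry the published rate constants.  ``a12`` is the open ->
    inactivated rate in ms^-1.  ``v_half_31`` is the half-voltage of the
    high-threshold closed -> open transition (its printed value differs
    between sources; -42 mV is the kinetic-scheme value and the one the
    bifurcation presets use).
    """
    tr = {
        (1, 2): ("const", a12),
        (1, 3): ("f1", RateParams(1 / 3, -51.0, -2.0)),
        (1, 4): ("f1", RateParams(1 / 3, -57.0, -2.0)),
        (2, 3): ("f2", RateParams(1.0, -53.0, -1.0, 100.0)),
        (3, 1): ("f1", RateParams(1 / 3, v_half_31, 1.0)),
        (3, 4): ("f2", RateParams(1.0, -60.0, -1.0, 100.0)),
        (4, 1): ("f1", RateParams(1 / 3, -51.0, 1.0)),
    }
    return MarkovNaParams(4, tr, g_na_bar, v_na)


def three_state_na(g_na_bar: float, v_na: float = 65.0, a12: float = 3.0,
                   v_half_31: float = -51.0) -> MarkovNaParams:
    """The 3-state reduction: the second closed state is dropped and the
    closed -> open half-voltage takes the low-threshold value (-51 mV by
    default; the bifurcation preset overrides it to -42 mV)."""
    tr = {
        (1, 2): ("const", a12),
        (1, 3): ("f1", RateParams(1 / 3, -51.0, -2.0)),
        (2, 3): ("f2", RateParams(1.0, -53.0, -1.0, 100.0)),
        (3, 1): ("f1", RateParams(1 / 3, v_half_31, 1.0)),
    }
    return MarkovNaParams(3, tr, g_na_bar, v_na)


@dataclass(frozen=True)
class ExpRateGate:
    """Gate with thermodynamic-form opening/closing rates.

    alpha(V) = a * exp(+slope_a * (V - v0)),
    beta(V)  = a_beta * exp(-slope_b * (V - v0))  (slope_b >= 0),
    x_inf = alpha/(alpha+beta), tau = 1/(alpha+beta) + tau_floor.

    The opposite signs of the two exponents follow the transition-state
    form of voltage-dependent rates; the printed prefactors and slopes are
    kept verbatim.
    """

    a: float          # ms^-1
    v0: float         # mV
    slope_a: float    # mV^-1, applied with + sign to alpha
    slope_b: float    # mV^-1, applied with - sign to beta
    tau_floor: float  # ms
    a_beta: float | None = None  # defaults to a

    def rates(self, v: float):
        ab = self.a if self.a_beta is None else self.a_beta
        alpha = self.a * np.exp(self.slope_a * (v - self.v0))
        beta = ab * np.exp(-self.slope_b * (v - self.v0))
        return alpha, beta

    def steady_state_tau(self, v: float):
        alpha, beta = self.rates(v)
        return alpha / (alpha + beta), 1.0 / (alpha + beta) + self.tau_floor


@dataclass(frozen=True)
class SigmoidGate:
    """Gate with a Boltzmann steady state and a fixed time constant.

    x_inf = 1 / (1 + exp(slope * (V - v_half))), tau = tau (ms).
    Positive ``slope`` gives a steady state that falls with depolarization
    (inactivation-type gates).
    """

    v_half: float   # mV
    slope: float    # mV^-1
    tau: float      # ms

    def steady_state_tau(self, v: float):
        return 1.0 / (1.0 + np.exp(self.slope * (v - self.v_half))), self.tau


@dataclass(frozen=True)
class GateParams:
    """Hodgkin-Huxley-type potassium-channel gating and conductances.

    Channels and their open fractions:

    * delayed rectifier (DR): ``n * yK``
    * A-type:                 ``nA**4 * lA**3``
    * M-type (KM):            ``nKM**2 * lKM``
    """

    g_dr_bar: float = 0.0
    g_a_bar: float = 0.0
    g_km_bar: float = 0.0
    v_k: float = -70.0

    n: ExpRateGate = field(default_factory=lambda: ExpRateGate(
        0.17, -5.0, 0.090, 0.022, 0.8))
    y_k: SigmoidGate = field(default_factory=lambda: SigmoidGate(
        -68.0, 0.038, 300.0))
    n_a: ExpRateGate = field(default_factory=lambda: ExpRateGate(
        0.08, -41.0, 0.089, 0.016, 1.0))
    # lA: alpha falls with V, beta is constant; expressed in the same
    # two-exponential form with slope_a < 0 and slope_b = 0.
    l_a: ExpRateGate = field(default_factory=lambda: ExpRateGate(
        0.04, -49.0, -0.11, 0.0, 2.0))
    n_km: ExpRateGate = field(default_factory=lambda: ExpRateGate(
        0.003, -45.0, 0.14, 0.094, 8.0))
    l_km: SigmoidGate = field(default_factory=lambda: SigmoidGate(
        -40.0, 0.2, 1000.0))

    def __post_init__(self) -> None:
        for g in (self.g_dr_bar, self.g_a_bar, self.g_km_bar):
            if g < 0:
                raise ValueError("conductances must be non-negative")


GATE_IDS = ("n", "y_k", "n_a", "l_a", "n_km", "l_km")


@dataclass(frozen=True)
class NeuronParams:
    """Full single-compartment model: leak, Markov Na, K channels, input.

    ``g_in`` is the input conductance used to normalize analysis axes
    (u/G_in, s/G_in); by default it equals the leak conductance.
    ``v_us`` is the reference potential of the shunt term of the injected
    current ``u - s (V - v_us)``.
    """

    c: float                      # pF or uF/cm2
    g_l: float                    # nS or uS/cm2
    v_l: float                    # mV
    na: MarkovNaParams
    gates: GateParams
    v_us: float = -60.0           # mV
    g_in: float | None = None     # defaults to g_l
    dialect: Dialect = "point"
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.c > 0):
            raise ValueError("capacitance must be positive")
        if self.g_l < 0:
            raise ValueError("leak conductance must be non-negative")
        for v in (self.v_l, self.v_us, self.na.v_na, self.gates.v_k):
            if not math.isfinite(v):
                raise ValueError("reversal/reference potentials must be finite")

    @property
    def input_conductance(self) -> float:
        return self.g_l if self.g_in is None else self.g_in

    @property
    def n_states(self) -> int:
        return self.na.n_states

    @property
    def state_dim(self) -> int:
        # V + (n_states - 1) independent occupancies + six gates
        return 1 + (self.na.n_states - 1) + 6

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["na"]["transitions"] = [
            {"from": i, "to": j, "kind": kind,
             "params": (val if kind == "const" else asdict_rate(val))}
            for (i, j), (kind, val) in sorted(self.na.transitions.items())
        ]
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronParams":
        d = dict(d)
        nad = dict(d.pop("na"))
        tr = {}
        for t in nad.pop("transitions"):
            kind = t["kind"]
            val = t["params"] if kind == "const" else RateParams(**_inf(t["params"]))
            tr[(t["from"], t["to"])] = (kind, val)
        na = MarkovNaParams(transitions=tr, **nad)
        gd = dict(d.pop("gates"))
        gates = GateParams(
            g_dr_bar=gd["g_dr_bar"], g_a_bar=gd["g_a_bar"],
            g_km_bar=gd["g_km_bar"], v_k=gd["v_k"],
            n=ExpRateGate(**gd["n"]), y_k=SigmoidGate(**gd["y_k"]),
            n_a=ExpRateGate(**gd["n_a"]), l_a=ExpRateGate(**gd["l_a"]),
            n_km=ExpRateGate(**gd["n_km"]), l_km=SigmoidGate(**gd["l_km"]),
        )
        return cls(na=na, gates=gates, **d)

    @classmethod
    def from_json(cls, path: str | Path) -> "NeuronParams":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NeuronParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def asdict_rate(r: RateParams) -> dict:
    d = asdict(r)
    if math.isinf(d["tau_max"]):
        d["tau_max"] = "inf"
    return d


def _inf(d: dict) -> dict:
    d = dict(d)
    if d.get("tau_max") == "inf":
        d["tau_max"] = math.inf
    return d
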