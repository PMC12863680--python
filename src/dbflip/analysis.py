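"""Operational excitability analysis of voltage traces.

Implements the study-style measures: threshold/refractory spike detection,
per-step firing rates, f-I curves, two-parameter f-u-s maps, entry into
depolarization block (DB), low-/high-frequency cell classification,
"flip" counting and action-potential features.

Definitions
-----------
* firing rate: spikes per stimulation window (500 ms by default), in Hz.
* DB entry: the smallest current beyond the f-I peak at which the rate has
  fallen to half its maximum; reported normalized by the input conductance
  as ``u_DB / G_in`` (mV).
* LFC / HFC: maximum rate below / at-or-above 12 Hz.
* full DB step: at most 2 spikes; spiking step: at least 3.
* flip: a transition from full DB back to spiking at a larger current
  step, counted only after a full-DB step that itself follows spiking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .membrane import Trace

__all__ = [
    "SpikeTrain", "FICurve", "FUSMap", "DBMetrics", "FlipReport",
    "APFeatures", "detect_spikes", "step_firing_rate", "build_fi_curve",
    "build_fus_map", "classify_cell", "find_db_entry", "count_flips",
    "ap_features", "LFC_HFC_SPLIT_HZ", "FULL_DB_MAX_SPIKES",
]

LFC_HFC_SPLIT_HZ = 12.0
FULL_DB_MAX_SPIKES = 2       # "only 1 or 2 action potentials"
DEFAULT_THRESHOLD_MV = -10.0
DEFAULT_REFRACTORY_MS = 2.0
MIN_SAMPLE_RATE_KHZ = 10.0


@dataclass
class SpikeTrain:
    times: np.ndarray          # ms, strictly increasing
    u: float | None = None
    s: float | None = None

    @property
    def count(self) -> int:
        return int(self.times.size)


@dataclass
class FICurve:
    """Firing rate versus injected current at fixed shunt conductance."""

    u: np.ndarray              # strictly increasing
    f: np.ndarray              # Hz
    s: float = 0.0
    g_in: float | None = None

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, float)
        self.f = np.asarray(self.f, float)
        if np.any(np.diff(self.u) <= 0):
            raise ValueError("u values must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"u": self.u, "f_Hz": self.f})

    def plot(self, ax=None, **kw):
        import matplotlib.pyplot as plt
        ax = ax or plt.gca()
        ax.plot(self.u, self.f, marker="o", **kw)
        ax.set_xlabel("injected current u")
        ax.set_ylabel("firing rate (Hz)")
        return ax


@dataclass
class FUSMap:
    """Firing rate over a rectangular (u, s) grid, axes scaled by G_in."""

    u: np.ndarray              # current axis
    s: np.ndarray              # conductance axis
    f: np.ndarray              # shape (len(s), len(u)), Hz
    g_in: float = 1.0

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, float)
        self.s = np.asarray(self.s, float)
        self.f = np.asarray(self.f, float)
        if self.f.shape != (self.s.size, self.u.size):
            raise ValueError("f must have shape (len(s), len(u))")
        if np.any(self.f < 0):
            raise ValueError("rates must be non-negative")

    @property
    def u_over_gin(self) -> np.ndarray:
        return self.u / self.g_in

    @property
    def s_over_gin(self) -> np.ndarray:
        return self.s / self.g_in

    def row(self, s: float) -> FICurve:
        i = int(np.argmin(np.abs(self.s - s)))
        if abs(self.s[i] - s) > 1e-9:
            raise KeyError(f"no grid row at s={s}")
        return FICurve(self.u, self.f[i], s=float(self.s[i]), g_in=self.g_in)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.f, index=pd.Index(self.s, name="s"),
                            columns=pd.Index(self.u, name="u"))

    def plot(self, ax=None, **kw):
        import matplotlib.pyplot as plt
        ax = ax or plt.gca()
        m = ax.pcolormesh(self.u_over_gin, self.s_over_gin, self.f,
                          shading="nearest", **kw)
        ax.set_xlabel("u / G_in (mV)")
        ax.set_ylabel("s / G_in")
        plt.colorbar(m, ax=ax, label="firing rate (Hz)")
        return ax


@dataclass
class DBMetrics:
    f_max: float               # Hz
    u_db: float | None         # None when DB is never reached in range
    g_in: float

    @property
    def defined(self) -> bool:
        return self.u_db is not None

    @property
    def u_db_over_gin(self) -> float | None:
        return None if self.u_db is None else self.u_db / self.g_in


@dataclass
class FlipReport:
    n_flips: int
    labels: list               # "DB" / "spiking" per step
    flip_indices: list = field(default_factory=list)
    counts: list = field(default_factory=list)


@dataclass
class APFeatures:
    peak: float                # mV
    amplitude: float           # mV, peak - RMP
    half_width: float          # ms


# ---------------------------------------------------------------------
# spike detection and rates
# ---------------------------------------------------------------------

def detect_spikes(trace: Trace, threshold: float = DEFAULT_THRESHOLD_MV,
                  refractory: float = DEFAULT_REFRACTORY_MS,
                  t_min: float | None = None,
                  smooth_ms: float = 0.0) -> SpikeTrain:
    """One spike per upward threshold crossing, enforcing a refractory gap.

    ``t_min`` discards an initial transient (crossings before it are
    ignored).  ``smooth_ms`` applies a boxcar low-pass of that width
    before detection, emulating the acquisition filter of whole-cell
    recordings; it suppresses measurement-noise chatter when the
    threshold must sit close to a silent plateau (reduced-amplitude
    spiking regimes).  The trace must be sampled at >= 10 kHz equivalent.
    """
    if trace.t.size < 2:
        raise ValueError("trace is empty or too short")
    if trace.dt > 1.0 / MIN_SAMPLE_RATE_KHZ:
        raise ValueError("trace must be sampled at >= 10 kHz equivalent")
    v, t = trace.v, trace.t
    if smooth_ms > 0:
        w = max(1, int(round(smooth_ms / trace.dt)))
        v = np.convolve(v, np.ones(w) / w, mode="same")
    idx = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold))
    times = []
    last = -np.inf
    for i in idx:
        # linear interpolation of the crossing time
        frac = (threshold - v[i]) / (v[i + 1] - v[i])
        tc = t[i] + frac * (t[i + 1] - t[i])
        if t_min is not None and tc < t_min:
            continue
        if tc - last >= refractory:
            times.append(tc)
            last = tc
    return SpikeTrain(np.asarray(times),
                      u=trace.meta.get("u"), s=trace.meta.get("s"))


def step_firing_rate(spikes: SpikeTrain, window: float = 500.0) -> float:
    """Spikes per stimulation window, in Hz."""
    if not window > 0:
        raise ValueError("window must be positive")
    return spikes.count / window * 1000.0


def _rate_of(trace: Trace, threshold, refractory, window, t_min,
             smooth_ms=0.0):
    sp = detect_spikes(trace, threshold, refractory, t_min=t_min,
                       smooth_ms=smooth_ms)
    return step_firing_rate(sp, window)


def build_fi_curve(traces, g_in: float | None = None, *,
                   threshold: float = DEFAULT_THRESHOLD_MV,
                   refractory: float = DEFAULT_REFRACTORY_MS,
                   window: float = 500.0,
                   t_min: float | None = None,
                   smooth_ms: float = 0.0) -> FICurve:
    """f-I curve from one trace per current step (fixed s).

    Each trace must carry its ``u`` (and ``s``) in ``meta``, as produced by
    the simulation and generator helpers.
    """
    rows = []
    for tr in traces:
        if tr.meta.get("u") is None:
            raise ValueError("each trace must carry meta['u']")
        rows.append((tr.meta["u"], _rate_of(tr, threshold, refractory,
                                            window, t_min, smooth_ms)))
    rows.sort()
    u, f = zip(*rows)
    s_vals = {tr.meta.get("s", 0.0) for tr in traces}
    if len(s_vals) > 1:
        raise ValueError("traces span multiple s values; use build_fus_map")
    return FICurve(np.array(u), np.array(f), s=s_vals.pop(), g_in=g_in)


def build_fus_map(traces, g_in: float, *,
                  threshold: float = DEFAULT_THRESHOLD_MV,
                  refractory: float = DEFAULT_REFRACTORY_MS,
                  window: float = 500.0,
                  t_min: float | None = None,
                  smooth_ms: float = 0.0) -> FUSMap:
    """f-u-s map from one trace per (u, s) grid point."""
    by_point = {}
    for tr in traces:
        u, s = tr.meta.get("u"), tr.meta.get("s")
        if u is None or s is None:
            raise ValueError("each trace must carry meta['u'] and meta['s']")
        by_point[(float(u), float(s))] = _rate_of(
            tr, threshold, refractory, window, t_min, smooth_ms)
    us = np.array(sorted({k[0] for k in by_point}))
    ss = np.array(sorted({k[1] for k in by_point}))
    missing = [(u, s) for s in ss for u in us if (u, s) not in by_point]
    if missing:
        raise ValueError(f"missing grid points: {missing}")
    f = np.array([[by_point[(u, s)] for u in us] for s in ss])
    return FUSMap(us, ss, f, g_in=g_in)


# ---------------------------------------------------------------------
# classification and DB metrics
# ---------------------------------------------------------------------

def classify_cell(f_max: float) -> str:
    """LFC below 12 Hz maximum rate, HFC at or above."""
    if f_max < 0:
        raise ValueError("f_max must be non-negative")
    return "LFC" if f_max < LFC_HFC_SPLIT_HZ else "HFC"


def find_db_entry(curve: FICurve, g_in: float | None = None,
                  interpolate: bool = False) -> DBMetrics:
    """DB entry current: first u past the f-I peak with f <= f_max / 2.

    Works on the discrete step grid by default; with ``interpolate`` the
    half-maximum crossing is located linearly between steps.  When the
    rate never falls to half maximum the metric is flagged undefined.
    """
    g_in = g_in if g_in is not None else (curve.g_in or 1.0)
    f_max = float(curve.f.max())
    if f_max <= 0:
        return DBMetrics(0.0, None, g_in)
    i_peak = int(np.argmax(curve.f))
    half = f_max / 2.0
    for i in range(i_peak + 1, curve.f.size):
        if curve.f[i] <= half:
            u_db = curve.u[i]
            if interpolate and curve.f[i - 1] > half:
                frac = (curve.f[i - 1] - half) / (curve.f[i - 1] - curve.f[i])
                u_db = curve.u[i - 1] + frac * (curve.u[i] - curve.u[i - 1])
            return DBMetrics(f_max, float(u_db), g_in)
    return DBMetrics(f_max, None, g_in)


def count_flips(counts, full_db_max: int = FULL_DB_MAX_SPIKES) -> FlipReport:
    """Count DB -> spiking resurgences in an ordered spike-count sequence.

    Steps with ``count <= full_db_max`` are labelled full DB, others
    spiking.  A flip is a DB -> spiking transition occurring after the
    first full-DB step that itself follows at least one spiking step, so
    subthreshold steps before the first spike never arm the counter.
    Trailing DB steps do not change the count.
    """
    counts = [int(c) for c in counts]
    if not counts:
        raise ValueError("empty spike-count sequence")
    labels = ["DB" if c <= full_db_max else "spiking" for c in counts]
    armed = False
    seen_spiking = False
    flips = []
    for i, lab in enumerate(labels):
        if lab == "spiking":
            if armed:
                flips.append(i)
                armed = False
            seen_spiking = True
        elif seen_spiking:
            armed = True
    return FlipReport(n_flips=len(flips), labels=labels,
                      flip_indices=flips, counts=counts)


def ap_features(trace: Trace, spike_time: float, rmp: float, *,
                search_ms: float = 10.0) -> APFeatures:
    """Amplitude (RMP to peak), peak voltage and half-width of one spike.

    The peak is the local maximum within ``search_ms`` after the detected
    crossing; the half-width is the time spent above RMP + amplitude/2
    around the peak.
    """
    if not (trace.t[0] <= spike_time <= trace.t[-1]):
        raise ValueError("spike time outside trace")
    i0 = int(np.searchsorted(trace.t, spike_time))
    i1 = int(np.searchsorted(trace.t, spike_time + search_ms))
    seg = trace.v[i0:i1]
    if seg.size < 3:
        raise ValueError("trace too short after spike time")
    ip = int(np.argmax(seg))
    if ip == 0 or ip == seg.size - 1 or seg[ip] <= rmp + 1e-9:
        raise ValueError("no local maximum found after the spike time")
    peak = float(seg[ip])
    amplitude = peak - rmp
    half_level = rmp + amplitude / 2.0
    # walk out from the peak to the half-level crossings
    j = ip
    while j > 0 and seg[j] > half_level:
        j -= 1
    t_left = _cross_time(trace.t[i0 + j], trace.t[i0 + j + 1],
                         seg[j], seg[j + 1], half_level)
    j = ip
    while j < seg.size - 1 and seg[j] > half_level:
        j += 1
    if seg[j] > half_level:
        raise ValueError("spike does not return below half amplitude")
    t_right = _cross_time(trace.t[i0 + j - 1], trace.t[i0 + j],
                          seg[j - 1], seg[j], half_level)
    return APFeatures(peak=peak, amplitude=amplitude,
                      half_width=float(t_right - t_left))


def _cross_time(t0, t1, v0, v1, level):
    if v1 == v0:
        return t0
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)
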