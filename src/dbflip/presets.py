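"""Named model presets and the synthetic-recording generator.

Presets come in two families:

* point-dialect cells (nS / pF / pA) for step-protocol simulation and
  trace analysis: the flipping reference cell, its Na-only reduction, and
  the LFC/HFC/flipper archetypes used to exercise the analysis pipeline;
* density-dialect parameter sets (uS/cm2 / uF/cm2 / uA/cm2) for the
  bifurcation analysis of the 3- and 4-state sodium models.

The generator turns a preset into a family of noisy "recorded" voltage
traces over a (u, s) step grid.  Every step is launched from the resting
state with the shunt engaged, as in a current-step family delivered from
rest.  Noise is additive Gaussian observation noise on V (default
0.3 mV); optional current process noise is off by default so generated
sets are exactly reproducible from their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .analysis import build_fi_curve, count_flips, detect_spikes
from .membrane import Trace, rest_state, step_response
from .params import (GateParams, NeuronParams, four_state_na, three_state_na)

__all__ = ["CellPreset", "list_presets", "get_preset",
           "generate_recording_set", "add_observation_noise",
           "density_neuron", "fig7_neuron"]


def fig7_neuron(n_states: int = 4, g_dr: float = 500.0, g_a: float = 0.0,
                g_km: float = 0.0, g_na: float = 228.0,
                v_half_31: float | None = None) -> NeuronParams:
    """Point-dialect reference cell of the flipping simulations.

    g_Na = 228 nS, g_DR = 500 nS, G_in (= leak) = 5 nS, C = 70 pF,
    V_L = -65 mV, V_us = -60 mV, V_K = -70 mV, V_Na = 65 mV.  The
    high-threshold closed -> open half-voltage keeps its kinetic-scheme
    default (-42 mV for the 4-state model, -51 mV for the 3-state
    reduction) unless overridden.
    """
    if n_states == 4:
        na = four_state_na(g_na, v_half_31=(-42.0 if v_half_31 is None
                                            else v_half_31))
    else:
        na = three_state_na(g_na, v_half_31=(-51.0 if v_half_31 is None
                                             else v_half_31))
    gates = GateParams(g_dr_bar=g_dr, g_a_bar=g_a, g_km_bar=g_km, v_k=-70.0)
    return NeuronParams(c=70.0, g_l=5.0, v_l=-65.0, na=na, gates=gates,
                        v_us=-60.0, dialect="point")


def density_neuron(n_states: int, v_us: float) -> NeuronParams:
    """Density-dialect parameter set of the bifurcation diagrams.

    g_Na = 2.28, g_DR = 0.76, g_A = 8.36, g_L = 0.048 uS/cm2,
    C = 0.7 uF/cm2, V_L = -64.96 mV, V_K = -70, V_Na = 65 mV; no KM
    current.  Both Na variants use the high-threshold closed -> open
    half-voltage of -42 mV, the value the diagrams are computed with.
    """
    na = (four_state_na(2.28, v_half_31=-42.0) if n_states == 4
          else three_state_na(2.28, v_half_31=-42.0))
    gates = GateParams(g_dr_bar=0.76, g_a_bar=8.36, g_km_bar=0.0, v_k=-70.0)
    return NeuronParams(c=0.7, g_l=0.048, v_l=-64.96, na=na, gates=gates,
                        v_us=v_us, dialect="density")


@dataclass(frozen=True)
class CellPreset:
    """Immutable named cell: model parameters plus default protocol.

    ``u_grid`` (current units) and ``s`` define the default step family;
    ``threshold`` is the spike-detection threshold suited to the preset's
    spike amplitudes (reduced-amplitude spiking regimes need a lower
    threshold than full-height spikes).
    """

    name: str
    params: NeuronParams
    u_grid: tuple
    s: float = 0.0
    step_ms: float = 700.0
    transient_ms: float = 200.0
    noise_sd: float = 0.3          # mV, observation noise
    noise_current_sd: float = 0.0  # process noise, off by default
    threshold: float = -10.0       # mV, spike detection
    smooth_ms: float = 0.0         # detection low-pass width
    expected_class: str | None = None
    expect_flipping: bool | None = None


def _u20(lo: float, hi: float) -> tuple:
    return tuple(np.linspace(lo, hi, 20))


def _build_registry() -> dict:
    reg = {}

    base4 = fig7_neuron(4)
    reg["fig7_4state"] = CellPreset(
        name="fig7_4state", params=replace(base4, name="fig7_4state"),
        u_grid=_u20(-200.0, 1200.0), s=0.0, expected_class="HFC")
    # the flipping protocol: shunt at four times the input conductance;
    # post-flip spikes peak near -35..-25 mV, hence the lower threshold,
    # which stays above the silent-gap plateau (about -41 mV).
    reg["flipper_like"] = CellPreset(
        name="flipper_like", params=replace(base4, name="flipper_like"),
        u_grid=_u20(-200.0, 1200.0), s=20.0, threshold=-38.0,
        smooth_ms=0.25, expect_flipping=True, expected_class="HFC")
    reg["fig7_na_only"] = CellPreset(
        name="fig7_na_only",
        params=replace(fig7_neuron(4, g_dr=0.0), name="fig7_na_only"),
        u_grid=_u20(-200.0, 1200.0), s=0.0)

    reg["fig8_3state"] = CellPreset(
        name="fig8_3state",
        params=replace(density_neuron(3, v_us=-49.0), name="fig8_3state"),
        u_grid=tuple(np.linspace(0.0, 3.0, 20)), s=0.2)
    reg["fig9_4state"] = CellPreset(
        name="fig9_4state",
        params=replace(density_neuron(4, v_us=-60.0), name="fig9_4state"),
        u_grid=tuple(np.linspace(0.0, 5.0, 20)), s=0.2)

    # archetypes: strong medium (KM) adaptation caps the rate of the
    # low-frequency cell; its protocol range matches the small currents
    # its high input resistance calls for.
    lfc = fig7_neuron(4, g_km=1500.0)
    reg["lfc_like"] = CellPreset(
        name="lfc_like", params=replace(lfc, name="lfc_like"),
        u_grid=tuple(np.linspace(0.0, 200.0, 6)), s=0.0,
        expected_class="LFC")
    hfc = fig7_neuron(4, g_km=20.0)
    reg["hfc_like"] = CellPreset(
        name="hfc_like", params=replace(hfc, name="hfc_like"),
        u_grid=tuple(np.linspace(0.0, 600.0, 6)), s=0.0,
        expected_class="HFC")
    return reg


_REGISTRY = _build_registry()


def list_presets() -> list:
    return sorted(_REGISTRY)


def get_preset(name: str) -> CellPreset:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {list_presets()}")


# ---------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------

def add_observation_noise(trace: Trace, sd: float,
                          rng: np.random.Generator) -> Trace:
    """Additive Gaussian measurement noise on the voltage samples."""
    noisy = Trace(trace.t.copy(), trace.v + rng.normal(0.0, sd, trace.v.size),
                  protocol=trace.protocol, meta=dict(trace.meta))
    return noisy


def generate_recording_set(preset: CellPreset, grid=None,
                           seed: int = 0) -> list:
    """Simulate one noisy trace per grid point; seed fixes the output.

    ``grid`` defaults to the preset's u-grid at its default shunt; a
    custom grid is either a sequence of u values or of (u, s) pairs.
    Each trace starts from the shunted resting state.
    """
    if grid is None:
        grid = [(u, preset.s) for u in preset.u_grid]
    else:
        grid = [(g, preset.s) if np.isscalar(g) else tuple(g) for g in grid]
    rng = np.random.default_rng(seed)
    rests = {}
    traces = []
    for u, s in grid:
        if s not in rests:
            rests[s] = rest_state(preset.params, s)
        tr = step_response(preset.params, u, s, duration=preset.step_ms,
                           init=rests[s])
        if preset.noise_sd > 0:
            tr = add_observation_noise(tr, preset.noise_sd, rng)
        tr.meta.update({"preset": preset.name, "seed": seed,
                        "u": u, "s": s})
        traces.append(tr)
    return traces


def write_recording_set(traces, out_dir: str | Path) -> Path:
    """Write traces as two-column CSVs plus a manifest JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, tr in enumerate(traces):
        fname = f"trace_{i:03d}.csv"
        tr.to_csv(out_dir / fname)
        manifest.append({"file": fname, **{k: tr.meta.get(k)
                                           for k in ("preset", "seed", "u", "s")}})
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir / "manifest.json"


def sweep_spike_counts(params: NeuronParams, u_values, s: float, *,
                       step_ms: float = 700.0, transient_ms: float = 200.0,
                       threshold: float = -30.0, refractory: float = 2.0,
                       smooth_ms: float = 0.0) -> list:
    """Spike count per step of an increasing-current family from rest.

    Each step runs for ``step_ms`` from the shunted resting state; the
    first ``transient_ms`` are discarded before counting.
    """
    init = rest_state(params, s)
    counts = []
    for u in u_values:
        tr = step_response(params, u, s, duration=step_ms, init=init)
        sp = detect_spikes(tr, threshold, refractory, t_min=transient_ms,
                           smooth_ms=smooth_ms)
        counts.append(sp.count)
    return counts


def flip_analysis(preset: CellPreset, u_values=None):
    """End-to-end flip counting for a preset's step family."""
    u_values = preset.u_grid if u_values is None else u_values
    counts = sweep_spike_counts(
        preset.params, u_values, preset.s, step_ms=preset.step_ms,
        transient_ms=preset.transient_ms, threshold=preset.threshold,
        smooth_ms=preset.smooth_ms)
    return count_flips(counts)


def classify_preset(preset: CellPreset, traces=None) -> str:
    """Max-rate LFC/HFC classification of a preset's recording set."""
    if traces is None:
        traces = generate_recording_set(preset)
    curve = build_fi_curve(traces, g_in=preset.params.input_conductance,
                           threshold=preset.threshold,
                           t_min=preset.transient_ms,
                           window=preset.step_ms - preset.transient_ms,
                           smooth_ms=preset.smooth_ms)
    from .analysis import classify_cell
    return classify_cell(float(curve.f.max()))


def read_recording_set(manifest_path: str | Path) -> list:
    manifest_path = Path(manifest_path)
    entries = json.loads(manifest_path.read_text())
    return [Trace.from_csv(manifest_path.parent / e["file"]) for e in entries]
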