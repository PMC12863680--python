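# Methods

## The model

`dbflip` simulates a single-compartment dentate-gyrus granule cell whose
membrane potential obeys

    C dV/dt = -g_L (V - V_L) - I_Na - I_DR - I_A - I_KM + u(t) - s(t) (V - V_us)

The injected current has the form used in conductance-injection (dynamic
clamp) experiments: a voltage-independent current `u` plus a shunt of
conductance `s` referenced to `V_us`. Any combination of
voltage-independent synaptic conductances reduces to this two-parameter
form, which is why excitability is mapped over the (u, s) plane rather
than over current alone. Both inputs are piecewise constant in time.

### Potassium currents

Three Hodgkin-Huxley-type currents:

* **Delayed rectifier** `I_DR = ḡ_DR · n · y_K · (V - V_K)` — fast spike
  repolarization; `n` activates (midpoint -5 mV), `y_K` is a slow
  inactivation gate (Boltzmann midpoint -68 mV, fixed τ = 300 ms).
* **A-type** `I_A = ḡ_A · n_A⁴ · l_A³ · (V - V_K)` — transient
  repolarizing current (activation midpoint -41 mV).
* **M-type** `I_KM = ḡ_KM · n_KM² · l_KM · (V - V_K)` — slow,
  medium-timescale adaptation (activation midpoint -45 mV; `l_KM` has a
  fixed τ = 1000 ms).

Rate-form gates use the transition-state convention
α = a·e^{+p(V-V₀)}, β = a·e^{-q(V-V₀)} with the printed prefactors and
slopes, x∞ = α/(α+β) and τ = 1/(α+β) plus an additive floor. The opposite
exponent signs follow from interpreting the forward/backward rates as
crossing one energy barrier with complementary electrical distances; this
convention is also the one that reproduces the published bifurcation
structure (see "Validation" below).

### Markov sodium channel

`I_Na = ḡ_Na · x₁ · (V - V_Na)` where `x₁` is the occupancy of the open
state of a continuous-time Markov chain with one open (1), one
inactivated (2) and one or two closed states (3, 4). Voltage-dependent
rates take one of two saturating forms,

    f1(V) = 1 / (τ_min + e^{-(V - V_half)/k})
    f2(V) = 1 / (τ_min + [ (τ_max - τ_min)^{-1} + e^{(V - V_half)/k} ]^{-1})

with f1 the τ_max → ∞ limit of f2 (the implementation makes this limit
exact). The two closed states carry different opening thresholds
(V_half(3→1) = -42 mV, V_half(4→1) = -51 mV), which gives the channel a
history-dependent threshold: during strong depolarization the population
cycles through the high-threshold closed state only, while
hyperpolarized interspike intervals recruit the low-threshold path. This
is the mechanical origin of the "flipping" phenomenon the package
analyses. The 3-state reduction drops state 4; its generic form takes
the low threshold (-51 mV), while the bifurcation presets use -42 mV,
the value the reference diagrams are computed with.

All seven printed transitions are implemented (4-state: 1→2, 1→3, 1→4,
2→3, 3→1, 3→4, 4→1); the open→closed deactivation rates (1→3, 1→4) are
physically necessary for recovery during repolarization and are supplied
with explicit parameters in the source scheme. The generator matrix has
columns summing to zero, and n-1 occupancies are integrated with the
last recovered by conservation (negative excursions below 1e-12 are
clamped).

## Unit dialects

Two self-consistent unit systems are supported and tagged on every
parameter set: a whole-cell "point" dialect (nS, pF, pA, mV, ms) and a
membrane-density dialect (µS/cm², µF/cm², µA/cm², mV, ms). Both satisfy
dV/dt = I/C in mV/ms, so the integrator is dialect-agnostic.

## Numerical choices

* **Integration**: LSODA (stiff-capable, adaptive), rtol 1e-6 / atol 1e-8
  by default, restarted at protocol-segment boundaries so input steps are
  sharp; dense 20 kHz sampling (0.05 ms), matching the digitization rate
  of the recordings the generator emulates. Refining tolerances tenfold
  moves spike times by < 0.1 ms on the reference presets.
* **Equilibria**: because every gate and the stationary Markov occupancy
  are explicit functions of voltage, the equilibrium curve is
  parametrized by V* and the balancing current is solved in closed form —
  no continuation is needed, and folds in u cost nothing.
* **Stability**: central finite-difference Jacobian (step 1e-6) of the
  conservation-reduced system; the reduction removes the zero eigenvalue
  of the redundant occupancy coordinate. The KM gates remain in the state
  vector even when ḡ_KM = 0; their eigenvalues are exactly -1/τ and
  cannot affect stability.
* **Hopf detection**: sign changes of the leading eigenvalue's real part
  along the branch, refined by bisection in V* to |Re λ| ≤ 1e-8, with the
  crossing required to be carried by a complex pair (ω > 0). Collisions
  of a complex pair on the positive real axis — which change the leading
  eigenvalue's character but not stability — are thereby excluded; each
  oscillatory window contributes exactly two Hopf points. Halving the
  grid spacing moves detected points by < 0.5 %.
* **Criticality**: simulation-based rather than normal-form reduction
  (robust for this 8-to-9-dimensional stiff system). The model is
  integrated just past the bifurcation at two parameter distances; an
  immediate large (≥ 15 mV) steady amplitude marks a subcritical Hopf, a
  small amplitude growing with distance a supercritical one, anything
  else is reported "undetermined" rather than guessed. The decision rule
  is validated against Hopf normal forms with known criticality.
* **Step protocols start from rest**: every step of a family is launched
  from the resting state with the shunt engaged, as in an experimental
  step family. This matters near subcritical window edges, where the
  attractor reached depends on the initial condition; the full
  spiking–silent–spiking "flip" structure at s/G_in = 4 is only visible
  from rest.

## Analysis definitions

* Spikes: upward threshold crossings (default -10 mV) separated by a
  2 ms refractory gap; crossing times linearly interpolated. An optional
  boxcar pre-filter emulates the acquisition low-pass; the flipping
  preset uses threshold -38 mV with a 0.25 ms filter because its
  post-flip spikes peak near -35..-25 mV while the silent-gap plateau
  sits near -41 mV.
* Firing rate: spikes per stimulation window (500 ms), in Hz.
* DB entry: smallest current beyond the f-I peak with f ≤ f_max/2,
  reported as u_DB/G_in (mV); discrete-grid by default, linear
  interpolation optional. Undefined (flagged, not raised) when the rate
  never falls to half maximum.
* LFC/HFC: maximum rate below / at-or-above 12 Hz (ties to HFC).
* Full DB step: ≤ 2 spikes; flip: a full-DB → spiking transition at
  larger current, counted only once DB has been established after
  spiking.
* Apparent activation/availability: stationary open-state occupancy
  (normalized to its grid maximum) and one minus the stationary
  inactivated occupancy, on -90..0 mV; half-voltages by linear
  interpolation of the first half-maximum crossing. This stationary
  definition is a declared convention of the package.

## Synthetic recordings

The generator emulates whole-cell voltage responses to 500–700 ms
current steps (-200..+1200 pA range for the point presets): deterministic
model traces plus seeded additive Gaussian observation noise (default
0.3 mV at 20 kHz); optional current process noise exists but is off by
default so outputs are exactly seed-reproducible. What it does *not*
emulate: access-resistance artifacts, liquid-junction drift, channel
stochasticity, electrode filtering beyond a simple boxcar, or biological
cell-to-cell variability. Passing the recovery tests therefore
demonstrates that the analysis pipeline is correct on model-generated
data with measurement noise, not that it is robust to every property of
real recordings.

The archetype presets are declared fixtures, not fits: `lfc_like` keeps
the reference cell's Na/DR conductances and adds strong M-type
adaptation (ḡ_KM = 1500 nS) with a 0–200 pA protocol matched to a
high-input-resistance cell, capping its maximum rate at 10 Hz;
`hfc_like` uses mild adaptation (ḡ_KM = 20 nS) and fires above 20 Hz;
`flipper_like` is the 4-state reference cell at s/G_in = 4.

## Bifurcation presets and known source ambiguities

The density-dialect presets reproduce the published two-window scenario:
the 3-state model has one oscillatory window bounded by Hopf points at
u ≈ 1.18 and 2.05; the 4-state model adds a second window (u ≈ 3.26 to
4.24) separated from the first by a stable depolarized state — the
depolarization-block state that flipping cells escape. The printed
parameter tables for these diagrams are internally inconsistent in two
places, and the presets carry the values that actually generate the
published structure: the shunt reference potential differs between the
two presets (-49 mV for the 3-state, -60 mV for the 4-state diagram),
and both use V_half(3→1) = -42 mV. The first window opens through a
subcritical Hopf and closes through a supercritical one in both models;
for the second window the classifier finds a subcritical onset and
supercritical offset (the source describes this pair inconsistently in
two places; the package reports what the dynamics show).

## Problem sizes

Default analysis scales, chosen to characterize the structure cleanly:
equilibrium branches on a 0.05 mV grid over -80..-10 mV (1400 points);
activation/availability on a 0.1 mV grid over -90..0 mV; flip sweeps of
20 steps of 700 ms (200 ms transient discarded); criticality probes at
two relative distances (0.5 % and 2 %) with 4 s integrations; oscillation
windows on 41-point current grids with 1.5 s integrations.

## Known limitations

* No periodic-orbit continuation: fold-of-cycles locations are not
  computed, so subcritical bistability windows are only probed by
  simulation.
* Criticality classification is asymptotic-simulation based and can
  return "undetermined" very close to degenerate (near-Bautin) points.
* The stationary activation/availability convention differs from
  pulse-protocol definitions used in voltage-clamp practice; both curves
  are exposed, but half-voltage values depend on the convention.
* The equilibrium parametrization by V* assumes all gates relax to
  unique steady states — true for this model family, not for models with
  bistable fast subsystems.
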