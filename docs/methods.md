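# Methods

## Scope and intent

`seqwta` emulates, in software, a serial-order memory architecture of the
kind built on mixed-signal neuromorphic processors: a small budget of
analog-style neurons (256), non-plastic synapses restricted to four
discrete excitatory levels plus a few inhibitory levels, plastic synapses
with analog weights that are binary in the long term, and external input
delivered as spike trains through "virtual synapses". The simulator is
clock-driven (forward Euler for the membrane, exact exponential factors
for all linear decays) with a one-time-step spike transmission delay,
which removes same-step causality ambiguity.

## Neuron model

Adaptive exponential integrate-and-fire:

    τ_m dV/dt = −(V − V_rest) + Δ_T exp((V − V_T)/Δ_T) + I_syn − I_adapt

A spike is registered when V crosses V_T + 5 Δ_T (Δ_T = 0 reduces to a
hard-threshold LIF, for which the closed-form rate
1/(t_ref + τ_m ln((I − (V_T − V_rest))/(I − (V_reset − V_rest)))) is used
as an independent oracle; the integrator agrees within 2% at
dt = 0.01 τ_m). After a spike the membrane is clamped at V_reset for the
refractory period, the adaptation current is incremented by `b` and
decays with τ_adapt, and the calcium trace is incremented by `c` and
decays with τ_Ca.

Voltages and currents are in arbitrary consistent units (V_rest = 0,
V_T = 1, R folded into the current scale); only time is physical (ms).
The hardware-parameter tables of such devices are not public, so the
default set below is the package's own, tuned once so that the standard
teaching protocol produces stable content bumps, self-sustained ordinal
and memory attractors, and clean CoS-driven transitions:

| parameter | default | role |
|---|---|---|
| τ_m | 20 ms | membrane integration |
| Δ_T | 0.1 | spike-initiation sharpness |
| t_ref | 4 ms | caps rates at 250 Hz |
| b, τ_adapt | 0.02, 100 ms | mild spike-frequency adaptation |
| c, τ_Ca | 1, 60 ms | Ca ≈ c·r·τ_Ca tracks the firing rate |
| τ_syn | 25 ms | PSC decay; long enough to bridge refractory gaps in recurrent attractors |

The synaptic time constant matters: with short PSCs (≈5 ms) an all-to-all
attractor of identical neurons synchronizes into volleys whose input
decays away during the shared refractory period, and the attractor
collapses when external drive is removed. τ_syn = 25 ms makes the
recurrent drive effectively tonic.

Device mismatch can be emulated with multiplicative Gaussian jitter
(`mismatch_sigma`, default 0 so that every run is exactly reproducible
from its seed; 0.05 is a hardware-like spread).

## Plasticity

The three-factor rule updates a plastic weight only at presynaptic spike
arrivals, from the postsynaptic membrane potential and calcium:
potentiation by Δw⁺ = 0.02 if V > θ_mem = 0.35 and θ₁ = 0.45 < Ca <
θ_max = 22; depression by Δw⁻ = 0.004 if V < θ_mem. For depression the
default calcium window is 0 ≤ Ca < θ_max ("low_inclusive"): a fully
silent postsynaptic neuron can be depressed. The shared-window variant
(θ₁ < Ca < θ_max for both directions) is available via
`PlasticityParams(ltd_gate="shared")`, but it cannot forget: overwriting
a stored sequence requires depressing synapses onto neurons that the
content WTA keeps silent, i.e. at Ca ≈ 0. The low calcium bound θ₁ still
gates potentiation, so a silent neuron can never be potentiated.

The bistable drift (C_drift = 1e-4 per ms toward the nearer of
w_min = 0/w_max = 1, threshold θ_w = 0.5) is deliberately slower than
sustained depression: a presynaptic rate of ~130 Hz depresses at
Δw⁻·r ≈ 5.2e-4 per ms, so a forgotten association crosses θ_w within one
teaching item, while isolated spurious updates are healed by the drift.
Drift runs whenever plasticity is enabled and is applied every time step
to the learnable block.

The transmitted efficacy of a plastic synapse is its analog weight times
a fixed gain (0.03), chosen so that a fully potentiated 20-neuron ordinal
projection drives a content neuron with slightly *less* current than the
external item input (≈1.9 vs ≈2.25 in threshold units). That inequality
is the overwrite condition: a new external item must be able to win the
content WTA against the recall of the old item.

## Architecture and layout

Populations are laid out contiguously (0-based): `cos` (10), `reset`
(10), `memory_1..K` (10 each), `ordinal_1..K` (20 each), `content_exc`
(60 for K ≤ 3, 40 otherwise), optional `content_inh` and `dvs_on`. The
total must fit the 256-neuron budget; the content field is the part that
shrinks for K = 5. Fields are linear — boundary neurons simply have
fewer excitatory neighbours, no wraparound.

Two soft-WTA patterns are provided: lateral (local excitation within a
radius, inhibition to every other neuron) and inhibitory-pool (local
excitation plus a small interneuron pool). The content field defaults to
the lateral pattern with radius 3.

Static weights use the four excitatory levels (0.1, 0.15, 0.25, 0.3) and
three inhibitory levels (−0.05, −0.3, −1.5): ordinal recurrence 0.15,
memory recurrence 0.25, ordinal→memory and memory→next-ordinal 0.1,
memory→own-ordinal −0.05 (the "already visited" bias), ordinal↔ordinal
and content-WTA inhibition −0.3, CoS→ordinal and reset→memory −1.5.
On top of the static recurrence, 30% of the entries of each ordinal and
memory recurrent block are potentiated plastic synapses at
initialisation; they are flagged non-learnable and act as extra
self-excitation. The ordinal→content block starts fully depressed and is
the only learnable part.

With these numbers the steady-state loop gains (n·w·τ_syn·r) put the
ordinal attractors at ~130–150 Hz and the memory attractors at
~170 Hz, both comfortably above the point where CoS (−1.5 level from 10
neurons at ~100 Hz) or reset inhibition extinguishes them, while the
content bump stays input-driven at ~50–160 Hz and collapses when its
drive is removed — which is what makes transitions work.

## Protocols

Teaching: go signal 3000 ms at 200 Hz to `ordinal_1`; each item 6000 ms
of Poisson drive with a Gaussian rate profile (peak 900 Hz, σ = 5
neurons for K = 3) over the content field plus uniform background noise
drawn once per epoch from [0, 10] Hz; a CoS trigger (500 ms, 800 Hz)
ends each item; the reset epoch (800 ms, 800 Hz) overlaps the final CoS
trigger so that no ordinal group re-ignites after the last transition.
Item centers are equally spaced at content_size/K with ±2σ item regions;
the σ default scales as content_size/(4K) so the regions stay disjoint
(σ = 5 for K = 3, σ = 2 for K = 5 on the reduced field).

Replay re-uses the go-signal parameters, stimulates nothing else, and
triggers CoS at scheduled times (arbitrary spacing; the decoded sequence
is invariant to spacings drawn from [1, 5] s). Plasticity is frozen
during replay and restored afterwards; on the emulated substrate the
bistable drift would protect the weights anyway, but freezing removes a
tuning-sensitive failure mode and matches the probe contract. Epochs in
which no content bump forms are reported as recall failures in the
result object rather than raised.

Unlearning teaches a new sequence over the old weights for up to
`n_trials` passes, probing and replaying after each. At the default
parameters the overwrite completes in a single trial (well inside the
≤ 4-trial bound the architecture is expected to meet), because
depression at ~130 Hz presynaptic drive erases a potentiated block
within one 6 s item presentation.

## Probe readout

Plastic weights cannot be observed directly; they are read out by
stimulating each synapse with a fixed regular burst (1800 Hz, 200 ms)
and recording whether the postsynaptic neuron fires. Each synapse is
probed in isolation against a fresh rest-state copy of its postsynaptic
neuron, so the probe is idempotent and leaves the network untouched; it
refuses to run while plasticity is enabled. With the default neuron
parameters the detection boundary sits near θ_w, and after drift the
weights are binary, far from the boundary.

## Event-camera front end

The synthetic DVS generator emulates a blinking laser pointer on a
128×128 sensor: Poisson events at the lit column (Gaussian pixel jitter,
σ = 1.5), uniform background noise, random polarities. Events map to
content neurons by linear binning of the x coordinate (polarity is
ignored) and every event also drives the `dvs_on` population, which
inhibits the CoS; the content field excites the CoS in this
configuration. When the laser switches off, `dvs_on` falls silent and
the still-active content bump activates the CoS, stepping the sequence —
so the laser's off-gaps, not a keystroke, time the transitions.

## What the synthetic data does and does not show

All inputs are generated (Poisson cues, background noise, synthetic
event streams); there is no recorded hardware data. Passing tests show
that the architecture's collective dynamics — bump formation, attractor
hand-off, one-shot binding, depression-driven forgetting — work as
designed under Poisson statistics and, optionally, parameter mismatch.
They do not show robustness to the full analog phenomenology of a
physical device (correlated parameter drift, temperature, synapse-level
stochasticity), nor to real camera data with structured clutter.

## Numerical choices and degenerate inputs

dt defaults to 0.1 ms (closed-form comparisons use 0.01·τ_m; the kernel
resolves 800 Hz inputs and the 4 ms refractory period comfortably).
Finiteness of the state is checked every 100 ms of simulated time; a
failure names the neuron and check step. Bump detection uses 100 ms
windows, a 40 Hz per-neuron threshold, and ≥ 3 contiguous neurons; a
sub-threshold gap of one window closes a bump. Decoding assigns a bump
to the item region containing its rate-weighted center when at least
half its spike mass falls inside (confidence ≥ 0.5); otherwise the bump
is reported unassigned rather than guessed. K = 1 sequences, empty
networks, empty rasters, and untaught replays are all defined: they
yield one-block matrices, empty rasters, empty bump lists, and
all-failed epochs respectively.

Experiment sizes used by the acceptance script — 10 seeds for the
overwrite count, 20 for the repeated-item replay — are the package's
default desk-scale study; each seed is an independent build-teach-replay
cycle of ~20–40 s simulated time.

## Known limitations

* Global parameters are shared across populations (as on the emulated
  substrate); per-population neuron parameters are not supported.
* The probe reads synapses in isolation; cross-talk during whole-network
  probing (WTA suppression among simultaneously driven posts) is not
  emulated.
* Short-term synaptic dynamics, conductance-based synapses, and
  transistor-level analog behaviour are out of scope.
* The robot loop stops at the decoded location sequence; no motor model.
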