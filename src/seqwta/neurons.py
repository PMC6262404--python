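"""Adaptive exponential integrate-and-fire neuron with a calcium trace.

The neuron model is the adaptive exponential integrate-and-fire (AdEx)
point neuron: a leaky membrane with an exponential spike-initiation term,
a subtractive spike-frequency adaptation current, and an absolute
refractory period during which the membrane is clamped at the reset
potential.  Each neuron additionally carries a calcium concentration
variable ``Ca`` — a low-pass filter of its own spike train — which acts
as the "third factor" gating synaptic plasticity.

Voltages and currents are in arbitrary but mutually consistent units
(membrane resistance is folded into the current scale); time is in
milliseconds.  Setting ``exponential_slope`` to 0 recovers the plain
leaky integrate-and-fire neuron, for which a closed-form firing rate
exists and is used as an independent check of the integrator.

The functions here are the scalar reference semantics; the vectorised
simulation loop in :mod:`seqwta._kernel` follows the same update order
step for step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "NeuronParams",
    "NeuronState",
    "integrate_step",
    "update_calcium",
    "lif_rate",
]


@dataclass(frozen=True)
class NeuronParams:
    """Parameters of one AdEx neuron.

    Attributes
    ----------
    membrane_time_constant : float
        Leak time constant of the membrane, ms.
    resting_potential : float
        Value the membrane relaxes to without input.
    spike_threshold : float
        Soft threshold of the exponential term; with
        ``exponential_slope == 0`` it is the hard firing threshold.
    exponential_slope : float
        Sharpness of spike initiation (voltage units).  0 disables the
        exponential term.  When > 0 a spike is registered once the
        membrane crosses ``spike_threshold + 5 * exponential_slope``.
    reset_potential : float
        Membrane value after a spike and during the refractory period.
    refractory_period : float
        Absolute refractory period, ms.
    adaptation_increment : float
        Current added to the adaptation variable at each spike.
    adaptation_time_constant : float
        Decay time constant of the adaptation current, ms.
    calcium_increment : float
        Amount added to the calcium trace at each spike (dimensionless).
    calcium_time_constant : float
        Decay time constant of the calcium trace, ms.
    """

    membrane_time_constant: float = 20.0
    resting_potential: float = 0.0
    spike_threshold: float = 1.0
    exponential_slope: float = 0.1
    reset_potential: float = 0.0
    refractory_period: float = 4.0
    adaptation_increment: float = 0.02
    adaptation_time_constant: float = 100.0
    calcium_increment: float = 1.0
    calcium_time_constant: float = 60.0

    def __post_init__(self) -> None:
        if self.membrane_time_constant <= 0:
            raise ValueError("membrane_time_constant must be > 0")
        if self.adaptation_time_constant <= 0:
            raise ValueError("adaptation_time_constant must be > 0")
        if self.calcium_time_constant <= 0:
            raise ValueError("calcium_time_constant must be > 0")
        if self.refractory_period < 0:
            raise ValueError("refractory_period must be >= 0")
        if self.spike_threshold <= self.reset_potential:
            raise ValueError("spike_threshold must exceed reset_potential")
        if self.exponential_slope < 0:
            raise ValueError("exponential_slope must be >= 0")

    @property
    def cutoff_potential(self) -> float:
        """Voltage at which a spike is registered."""
        if self.exponential_slope > 0:
            return self.spike_threshold + 5.0 * self.exponential_slope
        return self.spike_threshold


@dataclass
class NeuronState:
    """Dynamic state of one neuron."""

    membrane_potential: float = 0.0
    adaptation_current: float = 0.0
    calcium: float = 0.0
    refractory_remaining: float = 0.0

    def validate(self) -> None:
        for name in ("membrane_potential", "adaptation_current", "calcium"):
            if not math.isfinite(getattr(self, name)):
                raise FloatingPointError(
                    f"non-finite neuron state ({name}={getattr(self, name)!r}); "
                    "this usually signals a numerical blow-up — reduce dt"
                )
        if self.calcium < 0:
            self.calcium = 0.0


def integrate_step(
    state: NeuronState,
    params: NeuronParams,
    input_current: float,
    dt: float,
) -> tuple[NeuronState, bool]:
    """Advance one neuron by one Euler step of ``dt`` ms.

    Returns the new state and a flag indicating whether a spike was
    emitted during this step.  On a spike the membrane is reset, the
    refractory timer armed, and the adaptation and calcium variables
    incremented.  The calcium and adaptation decays use exact
    exponential factors; the membrane uses forward Euler (required by
    the exponential term).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if not math.isfinite(input_current):
        raise FloatingPointError("non-finite input current")
    state.validate()

    v = state.membrane_potential
    w = state.adaptation_current * math.exp(-dt / params.adaptation_time_constant)
    refr = state.refractory_remaining
    spiked = False

    if refr > 0:
        refr = max(0.0, refr - dt)
        v = params.reset_potential
    else:
        exp_term = 0.0
        if params.exponential_slope > 0:
            # guard the exponential against overflow far above threshold
            arg = (v - params.spike_threshold) / params.exponential_slope
            exp_term = params.exponential_slope * math.exp(min(arg, 16.0))
        dv = (
            -(v - params.resting_potential)
            + exp_term
            + input_current
            - state.adaptation_current
        ) * dt / params.membrane_time_constant
        v = v + dv
        if not math.isfinite(v):
            raise FloatingPointError(
                "membrane potential diverged (non-finite); dt too large?"
            )
        if v >= params.cutoff_potential:
            spiked = True
            v = params.reset_potential
            refr = params.refractory_period
            w += params.adaptation_increment

    new = NeuronState(
        membrane_potential=v,
        adaptation_current=w,
        calcium=state.calcium,
        refractory_remaining=refr,
    )
    return update_calcium(new, spiked, dt, params), spiked


def update_calcium(
    state: NeuronState, spiked: bool, dt: float, params: NeuronParams
) -> NeuronState:
    """Decay the calcium trace and add the spike increment if ``spiked``.

    Ca follows a first-order low-pass filter of the neuron's spike
    train: exponential decay with ``calcium_time_constant`` plus a jump
    of ``calcium_increment`` per spike, clamped at >= 0 against
    round-off.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    ca = state.calcium * math.exp(-dt / params.calcium_time_constant)
    if spiked:
        ca += params.calcium_increment
    return replace(state, calcium=max(ca, 0.0))


def lif_rate(params: NeuronParams, input_current: float) -> float:
    """Closed-form firing rate (kHz, i.e. spikes/ms) of the LIF limit.

    Valid for ``exponential_slope == 0`` and no adaptation.  Returns 0
    for subthreshold input.
    """
    drive = input_current
    gap_thr = params.spike_threshold - params.resting_potential
    gap_res = params.reset_potential - params.resting_potential
    if drive <= gap_thr:
        return 0.0
    t_isi = params.refractory_period + params.membrane_time_constant * math.log(
        (drive - gap_res) / (drive - gap_thr)
    )
    return 1.0 / t_isi
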