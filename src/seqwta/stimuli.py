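"""Stimulus epochs and Poisson spike-train generation.

External input reaches neurons through "virtual synapses": each external
spike injects a postsynaptic-current quantum equal to the epoch's
``weight``.  An epoch targets a contiguous neuron range with one of
three rate profiles:

* ``constant`` — every neuron in the range at the same rate (Hz);
* ``gaussian`` — rate at neuron j is ``peak * exp(-(j-center)^2/(2σ^2))``
  (a population-coded item cue);
* ``uniform_background`` — per-neuron rates drawn once, uniformly from
  ``[0, max_rate]``, then held for the whole epoch (sensory noise).

Spike counts per neuron and time step are Poisson with the profile's
instantaneous rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = ["StimulusEpoch", "epoch_rates", "make_poisson_input"]


@dataclass(frozen=True)
class StimulusEpoch:
    """One external stimulation episode."""

    target: tuple[int, int]  # [lo, hi) absolute neuron indices
    profile: str  # constant | gaussian | uniform_background
    start: float  # ms
    duration: float  # ms
    rate: float = 0.0  # Hz: constant rate, gaussian peak, or background max
    center: float = 0.0  # gaussian center, relative to target lo
    sigma: float = 1.0  # gaussian width in neurons
    weight: float = 0.5  # virtual-synapse PSC quantum per spike

    def __post_init__(self) -> None:
        lo, hi = self.target
        if not (0 <= lo < hi):
            raise ConfigurationError(f"bad epoch target range ({lo}, {hi})")
        if self.profile not in ("constant", "gaussian", "uniform_background"):
            raise ConfigurationError(f"unknown rate profile {self.profile!r}")
        if self.rate < 0:
            raise ConfigurationError("negative stimulus rate")
        if self.duration <= 0 or self.start < 0:
            raise ConfigurationError("epoch must have start >= 0, duration > 0")
        if self.profile == "gaussian" and self.sigma <= 0:
            raise ConfigurationError("gaussian profile needs sigma > 0")

    @property
    def end(self) -> float:
        return self.start + self.duration


def epoch_rates(epoch: StimulusEpoch, rng: np.random.Generator) -> np.ndarray:
    """Per-neuron rates (Hz) over the epoch's target range.

    For ``uniform_background`` the rates are drawn from ``rng`` once and
    held; the other profiles are deterministic.
    """
    lo, hi = epoch.target
    width = hi - lo
    if epoch.profile == "constant":
        return np.full(width, epoch.rate)
    if epoch.profile == "gaussian":
        j = np.arange(width, dtype=float)
        return epoch.rate * np.exp(
            -((j - epoch.center) ** 2) / (2.0 * epoch.sigma**2)
        )
    return rng.uniform(0.0, epoch.rate, size=width)


def make_poisson_input(
    epoch: StimulusEpoch, dt: float, seed: int
) -> np.ndarray:
    """Sampled external spike counts, shape ``(n_steps, range width)``.

    Counts at step t, neuron j are Poisson with mean ``rate_j * dt``;
    this is the same sampling scheme the simulation kernel applies
    internally, exposed for direct inspection and testing.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be > 0")
    rng = np.random.default_rng(seed)
    rates = epoch_rates(epoch, rng)
    n_steps = int(round(epoch.duration / dt))
    lam = rates * dt * 1e-3
    return rng.poisson(lam, size=(n_steps, rates.size))
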