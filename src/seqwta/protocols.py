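"""Teaching, replay, and unlearning protocols.

The stimulation schedule reproduces the standard bench protocol:

* **teaching** — the sequence is "launched" by stimulating the first
  ordinal group for 3000 ms at 200 Hz (the *go* signal); each item is a
  6000 ms Poisson drive to the content field with a Gaussian rate
  profile (peak 900 Hz, σ in neurons) centred on the item's location,
  on top of uniform 0–10 Hz background noise; each item ends with a
  500 ms / 800 Hz stimulation of the CoS group, which inhibits the
  ordinal groups and forces the transition; after the last item the
  reset group is driven to silence the memory groups.
* **replay** — go signal to the first ordinal group, no content input;
  CoS triggers at arbitrary (scheduled) times step the sequence through;
  content activity is driven purely through the learned plastic
  synapses and is decoded from the raster.
* **unlearning** — a previously taught network is re-taught a new
  sequence without resetting the weights; the external content input
  must be stronger than the potentiated plastic drive so the new item
  wins the content WTA, while depression gradually forgets the old
  associations.  Probe matrices are recorded after every trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .analysis import DecodedSequence, decode_sequence
from .errors import ConfigurationError
from .network import Network, SimulationConfig, SpikeRaster, run_simulation
from .probe import probe_plastic_weights
from .stimuli import StimulusEpoch

__all__ = [
    "TeachingProtocol",
    "TeachResult",
    "ReplayResult",
    "UnlearnResult",
    "run_teaching",
    "run_replay",
    "run_unlearning",
    "default_cos_schedule",
]


def _subseed(seed: int, salt: int) -> int:
    return int((int(seed) * 1000003 + salt * 7919 + 17) % (2**31 - 1))


@dataclass(frozen=True)
class TeachingProtocol:
    """Stimulation parameters of one teaching pass."""

    items: tuple[str, ...] = ("A", "B", "C")
    go_duration: float = 3000.0
    go_rate: float = 200.0
    cos_duration: float = 500.0
    cos_rate: float = 800.0
    item_duration: float = 6000.0
    item_peak_rate: float = 900.0
    noise_max_rate: float = 10.0
    reset_duration: float = 800.0
    reset_rate: float = 800.0
    tail: float = 400.0
    # virtual-synapse weights of the external drives
    go_weight: float = 0.6
    cos_weight: float = 0.3
    item_weight: float = 0.1
    reset_weight: float = 0.3

    def __post_init__(self) -> None:
        if not self.items:
            raise ConfigurationError("protocol needs at least one item")
        for f_ in ("go_rate", "cos_rate", "item_peak_rate", "noise_max_rate",
                   "reset_rate"):
            if getattr(self, f_) < 0:
                raise ConfigurationError(f"{f_} must be >= 0")

    @property
    def duration(self) -> float:
        return len(self.items) * self.item_duration + self.tail


@dataclass
class TeachResult:
    raster: SpikeRaster
    item_windows: list[tuple[float, float]]
    failures: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


@dataclass
class ReplayResult:
    raster: SpikeRaster
    decoded: DecodedSequence
    cos_times: list[float]
    failures: list[str] = field(default_factory=list)

    @property
    def labels(self) -> list[str | None]:
        return self.decoded.labels


@dataclass
class UnlearnResult:
    first_success_trial: int | None
    decoded_per_trial: list[list[str | None]]
    probes: list[np.ndarray]
    replays: list[ReplayResult]


def _teaching_epochs(
    network: Network, protocol: TeachingProtocol
) -> tuple[list[StimulusEpoch], list[tuple[float, float]]]:
    lay = network.layout
    ann = network.annotations
    centers = dict(zip(ann["item_labels"], ann["item_centers"]))
    sigma = ann["item_sigma"]
    c_lo, c_hi = lay.range_of("content_exc")
    K = len(protocol.items)
    D = protocol.item_duration
    epochs: list[StimulusEpoch] = []
    item_windows = []

    epochs.append(StimulusEpoch(
        target=lay.range_of("ordinal_1"), profile="constant",
        start=0.0, duration=protocol.go_duration,
        rate=protocol.go_rate, weight=protocol.go_weight,
    ))
    for i, label in enumerate(protocol.items):
        if label not in centers:
            raise ConfigurationError(
                f"unknown item {label!r}; network knows {sorted(centers)}"
            )
        start = i * D
        item_windows.append((start, start + D))
        epochs.append(StimulusEpoch(
            target=(c_lo, c_hi), profile="gaussian",
            start=start, duration=D,
            rate=protocol.item_peak_rate,
            center=centers[label] - c_lo, sigma=sigma,
            weight=protocol.item_weight,
        ))
        epochs.append(StimulusEpoch(
            target=lay.range_of("cos"), profile="constant",
            start=start + D - protocol.cos_duration,
            duration=protocol.cos_duration,
            rate=protocol.cos_rate, weight=protocol.cos_weight,
        ))
    if protocol.noise_max_rate > 0:
        epochs.append(StimulusEpoch(
            target=(c_lo, c_hi), profile="uniform_background",
            start=0.0, duration=K * D,
            rate=protocol.noise_max_rate, weight=protocol.item_weight,
        ))
    epochs.append(StimulusEpoch(
        target=lay.range_of("reset"), profile="constant",
        start=K * D - protocol.cos_duration,
        duration=protocol.reset_duration,
        rate=protocol.reset_rate, weight=protocol.reset_weight,
    ))
    return epochs, item_windows


def run_teaching(
    network: Network,
    protocol: TeachingProtocol,
    seed: int = 0,
    dt: float = 0.1,
    mismatch_sigma: float = 0.0,
    ordinal_rate_threshold: float = 20.0,
) -> TeachResult:
    """Teach one pass of ``protocol.items``; mutates the plastic weights.

    The network starts from rest with plasticity enabled.  The result
    reports, per item, whether the expected ordinal group was active
    (mean rate above ``ordinal_rate_threshold`` Hz in the second half of
    the item window); a silent ordinal group means the association could
    not form and is reported as a protocol failure with phase and time.
    """
    epochs, item_windows = _teaching_epochs(network, protocol)
    network.reset_state()
    network.set_plasticity(True)
    cfg = SimulationConfig(dt=dt, duration=protocol.duration, seed=seed,
                           mismatch_sigma=mismatch_sigma)
    raster = run_simulation(network, epochs, cfg)
    failures = []
    for i, (t0, t1) in enumerate(item_windows):
        lo, hi = network.layout.range_of(f"ordinal_{i + 1}")
        r = raster.population_rate(lo, hi, t0 + (t1 - t0) / 2,
                                   t1 - protocol.cos_duration)
        if r < ordinal_rate_threshold:
            failures.append(
                f"teaching item {i + 1} ({protocol.items[i]}): ordinal group "
                f"{i + 1} rate {r:.1f} Hz < {ordinal_rate_threshold} Hz in "
                f"[{t0:.0f}, {t1:.0f}) ms"
            )
    return TeachResult(raster=raster, item_windows=item_windows,
                       failures=failures)


def default_cos_schedule(
    n_items: int, spacing: float = 3500.0, start: float | None = None
) -> list[float]:
    """Regularly spaced CoS trigger times for a replay of ``n_items``."""
    start = spacing if start is None else start
    return [start + i * spacing for i in range(n_items)]


def run_replay(
    network: Network,
    cos_times: list[float] | None = None,
    protocol: TeachingProtocol | None = None,
    seed: int = 0,
    dt: float = 0.1,
    mismatch_sigma: float = 0.0,
    rate_threshold: float = 40.0,
    window: float = 100.0,
) -> ReplayResult:
    """Replay the stored sequence; content gets no external stimulation.

    The go signal re-uses the teaching parameters; transitions are
    triggered by CoS stimulations at ``cos_times`` (arbitrary spacing is
    allowed).  Plasticity is frozen for the duration of the replay and
    restored afterwards.  Epochs in which no content bump formed are
    recorded as recall failures in the result, not raised.
    """
    protocol = protocol or TeachingProtocol()
    lay = network.layout
    K = len(lay.group_names("ordinal"))
    if cos_times is None:
        cos_times = default_cos_schedule(K)
    cos_times = sorted(cos_times)
    if cos_times[0] <= protocol.go_duration:
        raise ConfigurationError(
            "first CoS trigger must come after the go signal ends"
        )
    duration = cos_times[-1] + max(protocol.cos_duration,
                                   protocol.reset_duration) + 200.0

    epochs = [StimulusEpoch(
        target=lay.range_of("ordinal_1"), profile="constant",
        start=0.0, duration=protocol.go_duration,
        rate=protocol.go_rate, weight=protocol.go_weight,
    )]
    for ct in cos_times:
        epochs.append(StimulusEpoch(
            target=lay.range_of("cos"), profile="constant",
            start=ct, duration=protocol.cos_duration,
            rate=protocol.cos_rate, weight=protocol.cos_weight,
        ))
    epochs.append(StimulusEpoch(
        target=lay.range_of("reset"), profile="constant",
        start=cos_times[-1], duration=protocol.reset_duration,
        rate=protocol.reset_rate, weight=protocol.reset_weight,
    ))

    was_on = network.plasticity_enabled
    network.set_plasticity(False)
    network.reset_state()
    cfg = SimulationConfig(dt=dt, duration=duration, seed=seed,
                           mismatch_sigma=mismatch_sigma)
    try:
        raster = run_simulation(network, epochs, cfg)
    finally:
        network.set_plasticity(was_on)

    bounds = [0.0] + [ct + protocol.cos_duration for ct in cos_times]
    windows = [(bounds[i], cos_times[i]) for i in range(len(cos_times))]
    decoded = decode_sequence(
        raster,
        item_regions=network.annotations["item_regions"],
        content_range=lay.range_of("content_exc"),
        epochs=windows,
        window=window,
        rate_threshold=rate_threshold,
    )
    failures = [
        f"replay epoch {i + 1} [{w[0]:.0f}, {w[1]:.0f}) ms: no content bump"
        for i, (w, it) in enumerate(zip(windows, decoded.items))
        if it.bump is None
    ]
    return ReplayResult(raster=raster, decoded=decoded,
                        cos_times=list(cos_times), failures=failures)


def external_dominance_margin(network: Network,
                              protocol: TeachingProtocol,
                              assumed_ordinal_rate: float = 80.0) -> float:
    """Steady-state external minus plastic drive onto a content neuron.

    Positive means the external item input can overcome a fully
    potentiated plastic projection, the condition for overwriting a
    stored sequence.
    """
    tau = network.static.table.psc_time_constant
    ext = protocol.item_weight * protocol.item_peak_rate * 1e-3 * tau
    cfg = network.config
    n_pre = network.layout.size_of("ordinal_1")
    plast = (network.plastic.gain * network.plastic.params.w_max
             * n_pre * assumed_ordinal_rate * 1e-3 * tau)
    del cfg
    return ext - plast


def run_unlearning(
    network: Network,
    new_items: tuple[str, ...],
    protocol: TeachingProtocol | None = None,
    n_trials: int = 6,
    seed: int = 0,
    dt: float = 0.1,
    mismatch_sigma: float = 0.0,
    stop_at_success: bool = False,
) -> UnlearnResult:
    """Overwrite a stored sequence by repeated teaching of a new one.

    The network must already hold a taught sequence.  Each trial teaches
    ``new_items`` once (plastic weights are *not* reset), probes the
    ordinal→content block, and replays.  Returns the first 1-based trial
    index at which the replay decodes ``new_items`` exactly, along with
    the per-trial probes and decodes.
    """
    protocol = replace(protocol or TeachingProtocol(), items=tuple(new_items))
    if external_dominance_margin(network, protocol) <= 0:
        warnings.warn(
            "external content input is not stronger than a fully potentiated "
            "plastic projection; the old item may win the content WTA and "
            "the sequence will not be overwritten",
            stacklevel=2,
        )
    ord_span = network.layout.span_of("ordinal")
    c_range = network.layout.range_of("content_exc")
    probes: list[np.ndarray] = []
    replays: list[ReplayResult] = []
    decoded: list[list[str | None]] = []
    first = None
    for trial in range(1, n_trials + 1):
        run_teaching(network, protocol, seed=_subseed(seed, trial),
                     dt=dt, mismatch_sigma=mismatch_sigma)
        network.set_plasticity(False)
        probes.append(probe_plastic_weights(
            network, pre_range=ord_span, post_range=c_range, dt=dt))
        rep = run_replay(network, protocol=protocol,
                         seed=_subseed(seed, 1000 + trial),
                         dt=dt, mismatch_sigma=mismatch_sigma)
        network.set_plasticity(True)
        replays.append(rep)
        decoded.append(rep.labels)
        if first is None and rep.labels == list(new_items):
            first = trial
            if stop_at_success:
                break
    return UnlearnResult(first_success_trial=first,
                         decoded_per_trial=decoded,
                         probes=probes, replays=replays)
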