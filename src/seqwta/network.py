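"""Network container, spike raster, and the simulation driver."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .builder import PopulationLayout
from .errors import ConfigurationError, NumericalError
from .neurons import NeuronParams
from .stimuli import StimulusEpoch, epoch_rates
from .synapses import PlasticSynapseMatrix, StaticSynapseMatrix

__all__ = ["SimulationConfig", "SpikeRaster", "Network", "run_simulation"]

_MISMATCH_FIELDS = (
    "membrane_time_constant",
    "spike_threshold",
    "refractory_period",
    "adaptation_increment",
    "calcium_increment",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Time step, duration, seed, and optional parameter mismatch.

    ``mismatch_sigma`` is the standard deviation of the multiplicative
    Gaussian jitter applied per neuron to a subset of neuron parameters,
    emulating device mismatch of an analog substrate.  It defaults to 0
    so runs are exactly reproducible from the seed alone; 0.05 gives a
    hardware-like spread.
    """

    dt: float = 0.1
    duration: float = 1000.0
    seed: int = 0
    mismatch_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")
        if self.duration < self.dt:
            raise ConfigurationError("duration must be >= dt")
        if self.mismatch_sigma < 0:
            raise ConfigurationError("mismatch_sigma must be >= 0")


@dataclass
class SpikeRaster:
    """Timestamped spike events ``(time_ms, neuron_index)``.

    Times are non-decreasing; indices lie in ``[0, n_neurons)``.
    """

    times: np.ndarray
    indices: np.ndarray
    n_neurons: int
    duration: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.times.shape != self.indices.shape:
            raise ConfigurationError("raster times/indices length mismatch")
        if self.times.size:
            if np.any(np.diff(self.times) < 0):
                raise ConfigurationError("raster times must be non-decreasing")
            if self.indices.min() < 0 or self.indices.max() >= self.n_neurons:
                raise ConfigurationError("raster neuron index out of range")

    @property
    def n_events(self) -> int:
        return self.times.size

    def window(self, t0: float, t1: float) -> "SpikeRaster":
        m = (self.times >= t0) & (self.times < t1)
        return SpikeRaster(self.times[m], self.indices[m],
                           self.n_neurons, self.duration)

    def select(self, lo: int, hi: int) -> "SpikeRaster":
        m = (self.indices >= lo) & (self.indices < hi)
        return SpikeRaster(self.times[m], self.indices[m],
                           self.n_neurons, self.duration)

    def population_rate(self, lo: int, hi: int,
                        t0: float | None = None,
                        t1: float | None = None) -> float:
        """Mean firing rate (Hz) per neuron of ``[lo, hi)`` in a window."""
        t0 = 0.0 if t0 is None else t0
        t1 = self.duration if t1 is None else t1
        if t1 <= t0 or hi <= lo:
            return 0.0
        m = ((self.indices >= lo) & (self.indices < hi)
             & (self.times >= t0) & (self.times < t1))
        return float(m.sum()) / (hi - lo) / ((t1 - t0) * 1e-3)

    def spike_times(self, neuron: int) -> np.ndarray:
        return self.times[self.indices == neuron]


@dataclass
class Network:
    """A complete simulated network.

    Bundles the population layout, the non-plastic connectivity, the
    plastic matrix (may be ``None`` for purely static networks), shared
    neuron parameters, and free-form annotations (item labels/regions
    for the serial-order architecture).  Neuron state persists across
    calls to :func:`run_simulation` until :meth:`reset_state`.
    """

    layout: PopulationLayout
    static: StaticSynapseMatrix
    plastic: PlasticSynapseMatrix | None = None
    params: NeuronParams = field(default_factory=NeuronParams)
    annotations: dict = field(default_factory=dict)
    config: object | None = None
    external_weights: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.layout.n_total
        if self.static.weights.shape != (n, n):
            raise ConfigurationError(
                f"static matrix {self.static.weights.shape} does not match "
                f"layout size {n}"
            )
        if self.plastic is not None and self.plastic.weights.shape != (n, n):
            raise ConfigurationError(
                f"plastic matrix {self.plastic.weights.shape} does not match "
                f"layout size {n}"
            )
        self.reset_state()

    @property
    def n_neurons(self) -> int:
        return self.layout.n_total

    @property
    def plasticity_enabled(self) -> bool:
        return self.plastic is not None and self.plastic.plasticity_enabled

    def set_plasticity(self, enabled: bool) -> None:
        if self.plastic is not None:
            self.plastic.plasticity_enabled = enabled

    def reset_state(self) -> None:
        """Return all neurons to rest (weights are left untouched)."""
        n = self.n_neurons
        self.v = np.full(n, self.params.resting_potential)
        self.adaptation = np.zeros(n)
        self.calcium = np.zeros(n)
        self.refractory = np.zeros(n)
        self.psc = np.zeros(n)

    def _param_arrays(self, mismatch_sigma: float, seed: int) -> dict:
        """Per-neuron parameter arrays with optional mismatch jitter."""
        n = self.n_neurons
        p = self.params
        arrays = {
            "tau_mem": np.full(n, p.membrane_time_constant),
            "v_rest": np.full(n, p.resting_potential),
            "v_thr": np.full(n, p.spike_threshold),
            "slope": np.full(n, p.exponential_slope),
            "v_reset": np.full(n, p.reset_potential),
            "t_refr": np.full(n, p.refractory_period),
            "b_adapt": np.full(n, p.adaptation_increment),
            "tau_adapt": np.full(n, p.adaptation_time_constant),
            "ca_inc": np.full(n, p.calcium_increment),
            "tau_ca": np.full(n, p.calcium_time_constant),
        }
        if mismatch_sigma > 0:
            rng = np.random.default_rng(np.uint32(seed) ^ np.uint32(0x5EED))
            name_map = {
                "membrane_time_constant": "tau_mem",
                "spike_threshold": "v_thr",
                "refractory_period": "t_refr",
                "adaptation_increment": "b_adapt",
                "calcium_increment": "ca_inc",
            }
            for f in _MISMATCH_FIELDS:
                key = name_map[f]
                jit = rng.normal(1.0, mismatch_sigma, size=n)
                arrays[key] = arrays[key] * np.clip(jit, 0.5, 1.5)
        arrays["v_cut"] = np.where(
            arrays["slope"] > 0,
            arrays["v_thr"] + 5.0 * arrays["slope"],
            arrays["v_thr"],
        )
        return arrays


def _compile_epochs(
    stimuli: list[StimulusEpoch], net: Network, cfg: SimulationConfig
):
    """Validate epochs and pack them into kernel arrays."""
    n_steps = int(round(cfg.duration / cfg.dt))
    rng = np.random.default_rng(np.uint32(cfg.seed) ^ np.uint32(0xBACC))
    m = len(stimuli)
    max_w = max((e.target[1] - e.target[0] for e in stimuli), default=1)
    ep_start = np.zeros(m, dtype=np.int64)
    ep_end = np.zeros(m, dtype=np.int64)
    ep_weight = np.zeros(m)
    ep_lo = np.zeros(m, dtype=np.int64)
    ep_hi = np.zeros(m, dtype=np.int64)
    ep_rates = np.zeros((m, max_w))
    for i, e in enumerate(stimuli):
        lo, hi = e.target
        if hi > net.n_neurons:
            raise ConfigurationError(
                f"stimulus target ({lo}, {hi}) exceeds network size "
                f"{net.n_neurons}"
            )
        if e.end > cfg.duration + 1e-9:
            raise ConfigurationError(
                f"stimulus epoch [{e.start}, {e.end}) ms outside the "
                f"simulation window [0, {cfg.duration}) ms"
            )
        ep_start[i] = int(round(e.start / cfg.dt))
        ep_end[i] = int(round(e.end / cfg.dt))
        ep_weight[i] = e.weight
        ep_lo[i], ep_hi[i] = lo, hi
        ep_rates[i, : hi - lo] = epoch_rates(e, rng)
    return n_steps, ep_start, ep_end, ep_weight, ep_lo, ep_hi, ep_rates


def run_simulation(
    network: Network,
    stimuli: list[StimulusEpoch],
    config: SimulationConfig,
    events: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> SpikeRaster:
    """Run the clock-driven simulation and return the spike raster.

    Deterministic given ``(config.seed, inputs)``.  ``events`` is an
    optional precomputed event-driven drive ``(step, neuron, amount)``
    sorted by step (used by the event-camera front end).  Plasticity is
    applied only while the network's plastic matrix has it enabled.
    Neuron state persists in ``network`` after the run; plastic weights
    are updated in place.
    """
    from . import _kernel

    n = network.n_neurons
    if n == 0:
        return SpikeRaster(np.empty(0), np.empty(0, dtype=np.int64), 0,
                           config.duration)
    (n_steps, ep_start, ep_end, ep_weight, ep_lo, ep_hi,
     ep_rates) = _compile_epochs(stimuli, network, config)
    arrays = network._param_arrays(config.mismatch_sigma, config.seed)

    if network.plastic is not None:
        wp = network.plastic.weights
        pp = network.plastic.params
        gain = network.plastic.gain
        learn = network.plastic.learnable
        learn_row = learn.any(axis=1)
        has_row = learn_row | (wp != 0).any(axis=1)
        cols = np.where(learn.any(axis=0))[0]
        rows = np.where(learn_row)[0]
        if cols.size:
            c_lo, c_hi = int(cols.min()), int(cols.max()) + 1
            d_lo, d_hi = int(rows.min()), int(rows.max()) + 1
            block = learn[d_lo:d_hi, c_lo:c_hi]
            if not block.all() or learn.sum() != block.size:
                raise ConfigurationError(
                    "learnable plastic entries must form one contiguous block"
                )
        else:
            c_lo = c_hi = d_lo = d_hi = 0
        plasticity_on = network.plastic.plasticity_enabled
        plast_args = (
            plasticity_on, learn_row, c_lo, c_hi,
            pp.theta_mem, pp.theta_1, pp.theta_max,
            pp.delta_w_plus, pp.delta_w_minus,
            pp.c_drift, pp.theta_w, pp.w_min, pp.w_max,
            pp.ltd_gate == "low_inclusive", d_lo, d_hi,
        )
    else:
        wp = np.zeros((n, n))
        gain = 0.0
        has_row = np.zeros(n, dtype=bool)
        plast_args = (
            False, np.zeros(n, dtype=bool), 0, 0,
            0.0, 0.0, 1.0, 1.0, 1.0, 0.0, 0.5, 0.0, 1.0, True, 0, 0,
        )

    if events is None:
        ev_step = np.empty(0, dtype=np.int64)
        ev_neuron = np.empty(0, dtype=np.int64)
        ev_amount = np.empty(0)
    else:
        ev_step, ev_neuron, ev_amount = events
        ev_step = np.asarray(ev_step, dtype=np.int64)
        ev_neuron = np.asarray(ev_neuron, dtype=np.int64)
        ev_amount = np.asarray(ev_amount, dtype=np.float64)
        if ev_step.size and np.any(np.diff(ev_step) < 0):
            raise ConfigurationError("event drive must be sorted by step")

    t_refr_min = max(float(arrays["t_refr"].min()), config.dt)
    cap = int(n * n_steps * config.dt / t_refr_min) + n + 16
    out_t = np.empty(cap)
    out_i = np.empty(cap, dtype=np.int64)

    dec_adapt = np.exp(-config.dt / arrays["tau_adapt"])
    dec_ca = np.exp(-config.dt / arrays["tau_ca"])
    dec_syn = float(np.exp(-config.dt / network.static.table.psc_time_constant))

    n_spikes, bad_step, bad_neuron = _kernel.simulate(
        n_steps, config.dt, np.uint32(config.seed),
        arrays["tau_mem"], arrays["v_rest"], arrays["v_thr"], arrays["slope"],
        arrays["v_cut"], arrays["v_reset"], arrays["t_refr"],
        arrays["b_adapt"], dec_adapt, arrays["ca_inc"], dec_ca,
        network.v, network.adaptation, network.calcium, network.refractory,
        network.psc,
        network.static.weights, wp, gain, has_row,
        *plast_args,
        dec_syn,
        ep_start, ep_end, ep_weight, ep_lo, ep_hi, ep_rates,
        ev_step, ev_neuron, ev_amount,
        out_t, out_i,
    )
    if bad_step >= 0:
        raise NumericalError(bad_step, bad_neuron,
                             "reduce dt or input weights")
    n_spikes = min(n_spikes, cap)
    return SpikeRaster(out_t[:n_spikes].copy(), out_i[:n_spikes].copy(),
                       n, config.duration)
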