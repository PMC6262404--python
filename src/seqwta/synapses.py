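"""Synapse matrices and the bistable calcium-gated plasticity rule.

Two kinds of synapses are modelled, mirroring a mixed-signal neuromorphic
substrate:

* **Non-plastic synapses** carry one of a small set of discrete weights —
  exactly four excitatory levels plus a few inhibitory levels — selected
  per connection from a :class:`StaticWeightTable`.

* **Plastic synapses** hold an analog weight ``w`` in ``[w_min, w_max]``
  updated by a three-factor rule at each presynaptic spike arrival: the
  weight is potentiated by ``Δw+`` if the postsynaptic membrane is above
  ``θ_mem`` (the neuron is about to spike) and depressed by ``Δw−`` if it
  is below (the neuron has just spiked or is silent), in both cases gated
  by the postsynaptic calcium concentration.  Superimposed on these jumps
  is a constant drift of rate ``C_drift`` toward ``w_max`` or ``w_min``
  depending on which side of the threshold ``θ_w`` the weight sits, which
  makes the synapse bistable — and hence binary in the long term.

Every spike, whether through a static or a plastic synapse, injects an
exponentially decaying postsynaptic current with amplitude proportional
to the weight; currents superpose linearly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "StaticWeightTable",
    "StaticSynapseMatrix",
    "PlasticityParams",
    "PlasticSynapseMatrix",
    "deliver_spikes",
    "plastic_update_on_pre",
    "drift_step",
    "initialize_plastic_matrix",
]


@dataclass(frozen=True)
class StaticWeightTable:
    """Discrete weight levels available to non-plastic synapses.

    ``excitatory_levels`` must contain exactly four strictly increasing
    positive values (the hardware constraint the simulator reproduces);
    ``inhibitory_levels`` are negative, ordered weakest to strongest.
    """

    excitatory_levels: tuple[float, ...] = (0.1, 0.15, 0.25, 0.3)
    inhibitory_levels: tuple[float, ...] = (-0.05, -0.3, -1.5)
    psc_time_constant: float = 25.0

    def __post_init__(self) -> None:
        exc = self.excitatory_levels
        if len(exc) != 4:
            raise ConfigurationError("exactly 4 excitatory levels required")
        if any(w <= 0 for w in exc) or any(
            b <= a for a, b in zip(exc, exc[1:])
        ):
            raise ConfigurationError(
                "excitatory levels must be positive and strictly increasing"
            )
        if any(w >= 0 for w in self.inhibitory_levels):
            raise ConfigurationError("inhibitory levels must be negative")
        if self.psc_time_constant <= 0:
            raise ConfigurationError("psc_time_constant must be > 0")

    @property
    def all_levels(self) -> tuple[float, ...]:
        return tuple(self.excitatory_levels) + tuple(self.inhibitory_levels)

    def validate_matrix(self, weights: np.ndarray) -> None:
        """Check every nonzero entry equals one of the table levels."""
        nz = weights[weights != 0]
        levels = np.array(self.all_levels)
        if nz.size and not np.all(np.isclose(nz[:, None], levels[None, :]).any(axis=1)):
            bad = nz[~np.isclose(nz[:, None], levels[None, :]).any(axis=1)]
            raise ConfigurationError(
                f"static weights not in the level table: {np.unique(bad)[:5]}"
            )


@dataclass
class StaticSynapseMatrix:
    """Dense non-plastic connectivity; entry [pre, post] is the weight."""

    weights: np.ndarray
    table: StaticWeightTable = field(default_factory=StaticWeightTable)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 2:
            raise ConfigurationError("static matrix must be 2-D")
        self.table.validate_matrix(self.weights)

    @property
    def n_pre(self) -> int:
        return self.weights.shape[0]

    @property
    def n_post(self) -> int:
        return self.weights.shape[1]


@dataclass(frozen=True)
class PlasticityParams:
    """Thresholds and magnitudes of the bistable three-factor rule.

    ``ltd_gate`` selects the calcium window for depression:

    * ``"low_inclusive"`` (default): depression requires only
      ``Ca < theta_max`` — a silent postsynaptic neuron (Ca = 0) can be
      depressed, which is what lets an old sequence be forgotten when a
      new one is taught over it.
    * ``"shared"``: depression uses the same window as potentiation,
      ``theta_1 < Ca < theta_max`` (the literal short-term rule).
    """

    theta_mem: float = 0.35
    theta_1: float = 0.45
    theta_max: float = 22.0
    delta_w_plus: float = 0.02
    delta_w_minus: float = 0.004
    c_drift: float = 0.0001
    theta_w: float = 0.5
    w_min: float = 0.0
    w_max: float = 1.0
    ltd_gate: str = "low_inclusive"

    def __post_init__(self) -> None:
        if not (self.w_min < self.theta_w < self.w_max):
            raise ConfigurationError("require w_min < theta_w < w_max")
        if self.delta_w_plus <= 0 or self.delta_w_minus <= 0:
            raise ConfigurationError("delta_w_plus/minus must be > 0")
        if not (self.theta_1 < self.theta_max):
            raise ConfigurationError("require theta_1 < theta_max")
        if self.c_drift < 0:
            raise ConfigurationError("c_drift must be >= 0")
        if self.ltd_gate not in ("low_inclusive", "shared"):
            raise ConfigurationError("ltd_gate must be 'low_inclusive' or 'shared'")


@dataclass
class PlasticSynapseMatrix:
    """Analog plastic weights plus the mask of entries that learn.

    ``weights[pre, post]`` is the analog weight in ``[w_min, w_max]``.
    ``learnable[pre, post]`` marks synapses subject to the plasticity
    rule; entries potentiated at initialisation to strengthen recurrent
    connections are excluded (they do not participate in learning).
    ``gain`` converts the analog weight into the postsynaptic-current
    amplitude so plastic efficacies are commensurate with the static
    weight levels.
    """

    weights: np.ndarray
    learnable: np.ndarray
    params: PlasticityParams = field(default_factory=PlasticityParams)
    gain: float = 0.03
    plasticity_enabled: bool = True

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.learnable = np.asarray(self.learnable, dtype=bool)
        if self.weights.shape != self.learnable.shape:
            raise ConfigurationError("weights/learnable shape mismatch")
        lo, hi = self.params.w_min, self.params.w_max
        if self.weights.size and (
            self.weights.min() < lo - 1e-12 or self.weights.max() > hi + 1e-12
        ):
            raise ConfigurationError("plastic weights outside [w_min, w_max]")

    def binary(self) -> np.ndarray:
        """Weights thresholded at theta_w into {0, 1}."""
        return (self.weights > self.params.theta_w).astype(np.int8)


def deliver_spikes(
    spike_indices: np.ndarray,
    matrix: StaticSynapseMatrix | PlasticSynapseMatrix,
) -> np.ndarray:
    """Instantaneous current increments caused by presynaptic spikes.

    Each presynaptic spike adds ``weight`` (times ``gain`` for plastic
    synapses) to the postsynaptic current of every target; simultaneous
    spikes superpose linearly.  The caller owns the exponential decay of
    the resulting current with ``psc_time_constant``.
    """
    spike_indices = np.asarray(spike_indices, dtype=np.int64)
    if isinstance(matrix, PlasticSynapseMatrix):
        w = matrix.weights * matrix.gain
    else:
        w = matrix.weights
    n_pre, n_post = w.shape
    if spike_indices.size and (
        spike_indices.min() < 0 or spike_indices.max() >= n_pre
    ):
        raise ConfigurationError("spike index out of range for synapse matrix")
    out = np.zeros(n_post)
    for j in spike_indices:
        out += w[j]
    return out


def plastic_update_on_pre(
    w: float,
    v_post: float,
    ca_post: float,
    params: PlasticityParams,
) -> float:
    """Weight jump at a presynaptic spike arrival.

    Potentiation (``+Δw+``) if the postsynaptic membrane is above
    ``θ_mem`` and Ca lies in ``(θ1, θmax)``; depression (``−Δw−``) if
    the membrane is below ``θ_mem`` and Ca lies in the depression
    window; otherwise unchanged.  The result is clamped to
    ``[w_min, w_max]``.
    """
    in_ltp = params.theta_1 < ca_post < params.theta_max
    if params.ltd_gate == "shared":
        in_ltd = in_ltp
    else:
        in_ltd = ca_post < params.theta_max
    if v_post > params.theta_mem and in_ltp:
        w = w + params.delta_w_plus
    elif v_post < params.theta_mem and in_ltd:
        w = w - params.delta_w_minus
    return min(max(w, params.w_min), params.w_max)


def drift_step(w: float, dt: float, params: PlasticityParams) -> float:
    """Constant-rate drift toward the nearer stable state.

    ``w`` above ``θ_w`` drifts up at ``C_drift`` per ms (capped at
    ``w_max``); below ``θ_w`` it drifts down (floored at ``w_min``);
    exactly at ``θ_w`` neither strict condition holds and the weight
    stays put.  Applied every time step, independent of spiking.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if w > params.theta_w:
        return min(w + params.c_drift * dt, params.w_max)
    if w < params.theta_w:
        return max(w - params.c_drift * dt, params.w_min)
    return w


def initialize_plastic_matrix(
    layout,
    recurrent_potentiated_fraction: float = 0.3,
    seed: int = 0,
    params: PlasticityParams | None = None,
    gain: float = 0.03,
) -> PlasticSynapseMatrix:
    """Initial plastic matrix for the serial-order architecture.

    The ordinal→content block starts fully depressed (``w_min``) and is
    the learnable part that will store the sequence.  Within-group
    recurrent blocks of the ordinal and memory populations receive the
    given fraction of randomly chosen entries potentiated to ``w_max``;
    these strengthen recurrent excitation on top of the non-plastic
    levels and are flagged non-learnable.

    Parameters
    ----------
    layout : PopulationLayout
        Provides ordinal/memory group index ranges and the content range.
    recurrent_potentiated_fraction : float
        Fraction (in [0, 1]) of each recurrent block potentiated at
        initialisation; the count per block is ``round(f * size**2)``.
    seed : int
        Seeds the choice of potentiated entries; same seed, same matrix.
    """
    if not (0.0 <= recurrent_potentiated_fraction <= 1.0):
        raise ConfigurationError("recurrent_potentiated_fraction outside [0, 1]")
    params = params or PlasticityParams()
    rng = np.random.default_rng(seed)
    n = layout.n_total
    weights = np.full((n, n), params.w_min, dtype=np.float64)
    learnable = np.zeros((n, n), dtype=bool)

    c_lo, c_hi = layout.range_of("content_exc")
    for name in layout.group_names("ordinal"):
        lo, hi = layout.range_of(name)
        learnable[lo:hi, c_lo:c_hi] = True

    for kind in ("ordinal", "memory"):
        for name in layout.group_names(kind):
            lo, hi = layout.range_of(name)
            size = (hi - lo) ** 2
            k = int(round(recurrent_potentiated_fraction * size))
            if k == 0:
                continue
            flat = rng.choice(size, size=k, replace=False)
            rows, cols = np.unravel_index(flat, (hi - lo, hi - lo))
            weights[rows + lo, cols + lo] = params.w_max

    return PlasticSynapseMatrix(
        weights=weights, learnable=learnable, params=params, gain=gain
    )
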