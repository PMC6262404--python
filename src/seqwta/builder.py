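"""Population layout and connectivity construction.

Builds the two soft winner-take-all (WTA) connectivity patterns and the
full serial-order network:

* ``build_wta_lateral`` — pattern A: each neuron excites itself and its
  nearest neighbours within a radius and inhibits every other neuron in
  the field (lateral inhibition, no separate interneurons).
* ``build_wta_pool`` — pattern B: local excitation as in A, plus a small
  inhibitory pool that is excited by all excitatory neurons and inhibits
  them all back; no direct excitatory-to-excitatory inhibition.
* ``build_serial_order`` — the sequence-memory architecture: K ordinal
  groups (position-in-sequence attractors, mutually inhibitory so only
  one can win), K self-sustaining memory groups that record progress and
  drive the *next* ordinal group, a content WTA field whose active
  location encodes the item, a condition-of-satisfaction (CoS) group
  that transiently inhibits all ordinal groups to force transitions, a
  reset group inhibiting the memories, and a plastic ordinal→content
  block where the sequence is stored.

Fields are linear (no wraparound); neuron indices are 0-based and
contiguous per population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .synapses import (
    PlasticityParams,
    StaticSynapseMatrix,
    StaticWeightTable,
    initialize_plastic_matrix,
)

__all__ = [
    "PopulationLayout",
    "WTAConfig",
    "SerialOrderConfig",
    "build_wta_lateral",
    "build_wta_pool",
    "build_serial_order",
    "NEURON_BUDGET",
]

NEURON_BUDGET = 256  # analog-neuron budget of the emulated device


@dataclass
class PopulationLayout:
    """Named, disjoint, contiguous index ranges for every population."""

    ranges: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        occupied = np.zeros(self.n_total, dtype=bool)
        for name, (lo, hi) in self.ranges.items():
            if not (0 <= lo < hi):
                raise ConfigurationError(f"bad range for {name}: ({lo}, {hi})")
            if occupied[lo:hi].any():
                raise ConfigurationError(f"population {name} overlaps another")
            occupied[lo:hi] = True
        if self.n_total > NEURON_BUDGET:
            sizes = {k: hi - lo for k, (lo, hi) in self.ranges.items()}
            raise ConfigurationError(
                f"layout needs {self.n_total} neurons, budget is "
                f"{NEURON_BUDGET}; per-population sizes: {sizes}"
            )

    @property
    def n_total(self) -> int:
        return max(hi for _, hi in self.ranges.values())

    def range_of(self, name: str) -> tuple[int, int]:
        try:
            return self.ranges[name]
        except KeyError:
            raise ConfigurationError(f"no population named {name!r}") from None

    def size_of(self, name: str) -> int:
        lo, hi = self.range_of(name)
        return hi - lo

    def group_names(self, prefix: str) -> list[str]:
        """Names like ``ordinal_1 .. ordinal_K``, in index order."""
        names = [n for n in self.ranges if n.startswith(prefix + "_")
                 and n.split("_")[-1].isdigit()]
        return sorted(names, key=lambda n: int(n.split("_")[-1]))

    def span_of(self, prefix: str) -> tuple[int, int]:
        """Covering range of all numbered groups with this prefix."""
        names = self.group_names(prefix)
        if not names:
            raise ConfigurationError(f"no groups with prefix {prefix!r}")
        los, his = zip(*(self.ranges[n] for n in names))
        return min(los), max(his)

    def __contains__(self, name: str) -> bool:
        return name in self.ranges

    def to_dict(self) -> dict[str, list[int]]:
        return {k: [lo, hi] for k, (lo, hi) in self.ranges.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationLayout":
        return cls({k: (int(v[0]), int(v[1])) for k, v in d.items()})


@dataclass(frozen=True)
class WTAConfig:
    """Parameters of a soft-WTA field.

    Weights must be levels of the static weight table.  ``pattern`` is
    ``"lateral"`` (A) or ``"inhibitory_pool"`` (B); ``pool_size`` and
    ``exc_to_inh_weight`` only apply to pattern B.
    """

    pattern: str = "lateral"
    excitatory_radius: int = 3
    self_weight: float = 0.25
    neighbor_weight: float = 0.25
    inhibition_weight: float = -0.3
    pool_size: int = 4
    exc_to_inh_weight: float = 0.1
    table: StaticWeightTable = field(default_factory=StaticWeightTable)

    def __post_init__(self) -> None:
        if self.pattern not in ("lateral", "inhibitory_pool"):
            raise ConfigurationError("pattern must be lateral|inhibitory_pool")
        if self.excitatory_radius < 1:
            raise ConfigurationError("excitatory_radius must be >= 1")
        levels = self.table.all_levels
        for w in (self.self_weight, self.neighbor_weight,
                  self.inhibition_weight, self.exc_to_inh_weight):
            if not any(np.isclose(w, lv) for lv in levels):
                raise ConfigurationError(
                    f"WTA weight {w} is not a static weight-table level"
                )


def build_wta_lateral(n: int, cfg: WTAConfig) -> StaticSynapseMatrix:
    """Pattern A: local excitation, inhibition to everyone else.

    Row i excites ``{j : |i-j| <= radius}`` (itself at ``self_weight``,
    neighbours at ``neighbor_weight``) and inhibits all other neurons.
    The field is linear: boundary neurons simply have fewer excitatory
    neighbours, no wraparound.
    """
    r = cfg.excitatory_radius
    if n <= 2 * r:
        raise ConfigurationError(
            f"population of {n} too small for excitatory radius {r}"
        )
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    w = np.where(dist <= r, cfg.neighbor_weight, cfg.inhibition_weight)
    np.fill_diagonal(w, cfg.self_weight)
    return StaticSynapseMatrix(weights=w, table=cfg.table)


def build_wta_pool(n_exc: int, n_inh: int, cfg: WTAConfig) -> StaticSynapseMatrix:
    """Pattern B: local excitation plus a shared inhibitory pool.

    Matrix is ``(n_exc + n_inh)`` square with the excitatory field first.
    Excitatory neurons keep the local excitation of pattern A but no
    long-range inhibition; all of them excite every pool neuron, and
    every pool neuron inhibits every excitatory neuron.  The pool has no
    recurrent coupling onto itself.
    """
    if n_inh < 1:
        raise ConfigurationError("pattern B needs at least one pool neuron")
    r = cfg.excitatory_radius
    if n_exc <= 2 * r:
        raise ConfigurationError(
            f"population of {n_exc} too small for excitatory radius {r}"
        )
    n = n_exc + n_inh
    w = np.zeros((n, n))
    idx = np.arange(n_exc)
    dist = np.abs(idx[:, None] - idx[None, :])
    local = np.where(dist <= r, cfg.neighbor_weight, 0.0)
    np.fill_diagonal(local, cfg.self_weight)
    w[:n_exc, :n_exc] = local
    w[:n_exc, n_exc:] = cfg.exc_to_inh_weight
    w[n_exc:, :n_exc] = cfg.inhibition_weight
    return StaticSynapseMatrix(weights=w, table=cfg.table)


@dataclass(frozen=True)
class SerialOrderConfig:
    """Full parameterisation of the serial-order network.

    ``n_items`` is the sequence length K.  ``content_size`` and
    ``item_sigma`` default to 60 neurons / σ=5 for K ≤ 3 and to a
    reduced field of 40 neurons / σ=2 for longer sequences (the item
    spacing must stay ≥ 4σ so the ±2σ item regions are disjoint, and the
    whole layout must fit the neuron budget).

    All inter-population weights are levels of the static weight table;
    the signs encode synapse type.  ``content_to_cos_weight`` is zero in
    the default (externally triggered CoS) configuration and positive in
    the sensor-driven configuration, where the ``dvs_on`` population
    inhibits the CoS while events arrive.
    """

    n_items: int = 3
    ordinal_size: int = 20
    memory_size: int = 10
    cos_size: int = 10
    reset_size: int = 10
    content_size: int | None = None
    item_sigma: float | None = None
    include_dvs_on: bool = False
    dvs_on_size: int = 10
    # projections (static weight-table levels)
    ordinal_recurrent_weight: float = 0.15
    ordinal_inhibition_weight: float = -0.3
    ordinal_to_memory_weight: float = 0.1
    memory_recurrent_weight: float = 0.25
    memory_to_next_ordinal_weight: float = 0.1
    memory_to_own_ordinal_weight: float = -0.05
    cos_to_ordinal_weight: float = -1.5
    reset_to_memory_weight: float = -1.5
    content_to_cos_weight: float = 0.0
    dvs_on_to_cos_weight: float = -1.5
    content_wta: WTAConfig = field(default_factory=WTAConfig)
    # plastic block
    recurrent_potentiated_fraction: float = 0.3
    plastic_gain: float = 0.03
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    table: StaticWeightTable = field(default_factory=StaticWeightTable)
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ConfigurationError("n_items must be >= 1")

    @property
    def content_n(self) -> int:
        if self.content_size is not None:
            return self.content_size
        return 60 if self.n_items <= 3 else 40

    @property
    def sigma(self) -> float:
        if self.item_sigma is not None:
            return self.item_sigma
        return self.content_n / (4.0 * self.n_items)

    @property
    def item_labels(self) -> list[str]:
        return [chr(ord("A") + i) for i in range(self.n_items)]

    @property
    def item_centers(self) -> list[float]:
        """Equally spaced centers within the content field (relative)."""
        spacing = self.content_n / self.n_items
        centers = [(i + 0.5) * spacing for i in range(self.n_items)]
        if any(b - a < 2 * self.sigma - 1e-9
               for a, b in zip(centers, centers[1:])):
            raise ConfigurationError(
                "item centers closer than 2 sigma; shrink item_sigma or "
                "enlarge content field"
            )
        return centers

    def item_regions(self, layout: PopulationLayout) -> dict[str, tuple[int, int]]:
        """Absolute neuron-index ranges (center ± 2σ) per item label."""
        c_lo, _ = layout.range_of("content_exc")
        half = 2.0 * self.sigma
        regions = {}
        for lab, c in zip(self.item_labels, self.item_centers):
            lo = c_lo + int(np.floor(c - half))
            hi = c_lo + int(np.ceil(c + half))
            regions[lab] = (max(lo, c_lo), min(hi, c_lo + self.content_n))
        return regions


def _make_layout(cfg: SerialOrderConfig) -> PopulationLayout:
    ranges: dict[str, tuple[int, int]] = {}
    cursor = 0

    def add(name: str, size: int) -> None:
        nonlocal cursor
        ranges[name] = (cursor, cursor + size)
        cursor += size

    add("cos", cfg.cos_size)
    add("reset", cfg.reset_size)
    for k in range(1, cfg.n_items + 1):
        add(f"memory_{k}", cfg.memory_size)
    for k in range(1, cfg.n_items + 1):
        add(f"ordinal_{k}", cfg.ordinal_size)
    add("content_exc", cfg.content_n)
    if cfg.content_wta.pattern == "inhibitory_pool":
        add("content_inh", cfg.content_wta.pool_size)
    if cfg.include_dvs_on:
        add("dvs_on", cfg.dvs_on_size)
    return PopulationLayout(ranges)


def build_serial_order(cfg: SerialOrderConfig):
    """Assemble the serial-order network.

    Returns a :class:`seqwta.network.Network` holding the static matrix,
    the initialised plastic matrix, the layout, and item annotations
    (labels, centers, σ, regions).
    """
    from .network import Network  # deferred: network imports builder types

    layout = _make_layout(cfg)
    n = layout.n_total
    w = np.zeros((n, n))
    K = cfg.n_items

    ords = [layout.range_of(f"ordinal_{k}") for k in range(1, K + 1)]
    mems = [layout.range_of(f"memory_{k}") for k in range(1, K + 1)]
    c_lo, c_hi = layout.range_of("content_exc")
    cos_lo, cos_hi = layout.range_of("cos")
    rst_lo, rst_hi = layout.range_of("reset")

    # ordinal groups: all-to-all recurrent excitation, mutual inhibition
    for i, (lo, hi) in enumerate(ords):
        w[lo:hi, lo:hi] = cfg.ordinal_recurrent_weight
        for j, (lo2, hi2) in enumerate(ords):
            if i != j:
                w[lo:hi, lo2:hi2] = cfg.ordinal_inhibition_weight

    for k in range(K):
        olo, ohi = ords[k]
        mlo, mhi = mems[k]
        w[olo:ohi, mlo:mhi] = cfg.ordinal_to_memory_weight
        w[mlo:mhi, mlo:mhi] = cfg.memory_recurrent_weight
        w[mlo:mhi, olo:ohi] = cfg.memory_to_own_ordinal_weight
        if k + 1 < K:
            nlo, nhi = ords[k + 1]
            w[mlo:mhi, nlo:nhi] = cfg.memory_to_next_ordinal_weight

    # content WTA field
    if cfg.content_wta.pattern == "lateral":
        field_m = build_wta_lateral(cfg.content_n, cfg.content_wta)
        w[c_lo:c_hi, c_lo:c_hi] = field_m.weights
    else:
        i_lo, i_hi = layout.range_of("content_inh")
        field_m = build_wta_pool(
            cfg.content_n, cfg.content_wta.pool_size, cfg.content_wta
        )
        ne = cfg.content_n
        w[c_lo:c_hi, c_lo:c_hi] = field_m.weights[:ne, :ne]
        w[c_lo:c_hi, i_lo:i_hi] = field_m.weights[:ne, ne:]
        w[i_lo:i_hi, c_lo:c_hi] = field_m.weights[ne:, :ne]

    # CoS inhibits all ordinal groups; content may drive CoS (sensor mode)
    olo_all, ohi_all = layout.span_of("ordinal")
    w[cos_lo:cos_hi, olo_all:ohi_all] = cfg.cos_to_ordinal_weight
    if cfg.content_to_cos_weight:
        w[c_lo:c_hi, cos_lo:cos_hi] = cfg.content_to_cos_weight

    # reset silences the memories
    mlo_all, mhi_all = layout.span_of("memory")
    w[rst_lo:rst_hi, mlo_all:mhi_all] = cfg.reset_to_memory_weight

    if cfg.include_dvs_on and cfg.dvs_on_to_cos_weight:
        d_lo, d_hi = layout.range_of("dvs_on")
        w[d_lo:d_hi, cos_lo:cos_hi] = cfg.dvs_on_to_cos_weight

    static = StaticSynapseMatrix(weights=w, table=cfg.table)
    plastic = initialize_plastic_matrix(
        layout,
        recurrent_potentiated_fraction=cfg.recurrent_potentiated_fraction,
        seed=cfg.init_seed,
        params=cfg.plasticity,
        gain=cfg.plastic_gain,
    )
    annotations = {
        "item_labels": cfg.item_labels,
        "item_centers": [c_lo + c for c in cfg.item_centers],
        "item_sigma": cfg.sigma,
        "item_regions": cfg.item_regions(layout),
    }
    return Network(
        layout=layout, static=static, plastic=plastic,
        annotations=annotations, config=cfg,
    )
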