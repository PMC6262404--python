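"""Raster analysis: bump detection, sequence decoding, probe scoring.

A "bump" is a contiguous supra-threshold region of population activity
in the content field, the signature of the WTA attractor.  Bumps are
found on a (time-bin × neuron) rate map: per bin, contiguous runs of
neurons whose rate exceeds the threshold are merged with overlapping
runs in adjacent bins; a sub-threshold gap of at least one window closes
a bump.  Decoding assigns each bump to the item region containing its
rate-weighted center, with a confidence equal to the fraction of its
spike mass inside that region; low-confidence bumps are flagged
unassigned rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .network import SpikeRaster

__all__ = [
    "Bump",
    "DecodedItem",
    "DecodedSequence",
    "ProbeScore",
    "detect_bumps",
    "decode_sequence",
    "score_probe",
    "plot_raster",
]


@dataclass
class Bump:
    """One contiguous episode of localized supra-threshold activity."""

    onset: float  # ms
    offset: float  # ms
    center: float  # rate-weighted mean neuron index
    width: float  # mean supra-threshold run width, neurons
    mass: int  # spike count

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ConfigurationError("bump offset must exceed onset")


@dataclass
class DecodedItem:
    label: str | None  # None = unassigned
    bump: Bump | None
    confidence: float = 0.0

    @property
    def assigned(self) -> bool:
        return self.label is not None


@dataclass
class DecodedSequence:
    items: list[DecodedItem] = field(default_factory=list)

    @property
    def labels(self) -> list[str | None]:
        return [it.label for it in self.items]


@dataclass
class ProbeScore:
    """Block-level summary of a binary probe matrix."""

    block_fractions: dict[tuple[str, str], float]
    off_block_noise: float
    winners: dict[str, str | None]


def detect_bumps(
    raster: SpikeRaster,
    neuron_range: tuple[int, int],
    window: float = 100.0,
    rate_threshold: float = 40.0,
    min_neurons: int = 3,
    t0: float = 0.0,
    t1: float | None = None,
) -> list[Bump]:
    """Find activity bumps of ``neuron_range`` in ``[t0, t1)``.

    ``window`` (ms) is both the rate-estimation bin and the minimal gap
    separating two bumps; ``rate_threshold`` (Hz) is the per-neuron rate
    defining supra-threshold activity; runs narrower than
    ``min_neurons`` are ignored as noise.
    """
    if window <= 0:
        raise ConfigurationError("window must be > 0")
    lo, hi = neuron_range
    t1 = raster.duration if t1 is None else t1
    sub = raster.window(t0, t1).select(lo, hi)
    if sub.n_events == 0:
        return []
    n_bins = max(1, int(np.ceil((t1 - t0) / window)))
    counts, _, _ = np.histogram2d(
        sub.times, sub.indices,
        bins=[n_bins, hi - lo],
        range=[[t0, t0 + n_bins * window], [lo, hi]],
    )
    rates = counts / (window * 1e-3)
    active = rates >= rate_threshold

    bumps: list[Bump] = []
    open_runs: list[dict] = []
    for b in range(n_bins):
        runs = _runs(active[b], min_neurons)
        matched = set()
        new_open = []
        for r_lo, r_hi in runs:
            best = None
            for k, o in enumerate(open_runs):
                if k in matched:
                    continue
                if r_lo < o["hi"] and o["lo"] < r_hi:
                    best = k
                    break
            bin_mass = counts[b, r_lo:r_hi].sum()
            c = ((lo + np.arange(r_lo, r_hi)) * counts[b, r_lo:r_hi]).sum()
            if best is None:
                new_open.append({
                    "lo": r_lo, "hi": r_hi, "first_bin": b, "last_bin": b,
                    "mass": bin_mass, "csum": c,
                    "wsum": r_hi - r_lo, "wn": 1,
                })
            else:
                o = open_runs[best]
                matched.add(best)
                o.update(lo=r_lo, hi=r_hi, last_bin=b)
                o["mass"] += bin_mass
                o["csum"] += c
                o["wsum"] += r_hi - r_lo
                o["wn"] += 1
                new_open.append(o)
        for k, o in enumerate(open_runs):
            if k not in matched:  # no overlapping run this bin: gap, close
                bumps.append(_close(o, window, t0))
        open_runs = new_open
    bumps.extend(_close(o, window, t0) for o in open_runs)
    bumps.sort(key=lambda bp: bp.onset)
    return bumps


def _runs(active_row: np.ndarray, min_neurons: int) -> list[tuple[int, int]]:
    padded = np.concatenate(([False], active_row, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.where(d == 1)[0]
    stops = np.where(d == -1)[0]
    return [(a, b) for a, b in zip(starts, stops) if b - a >= min_neurons]


def _close(o: dict, window: float, t0: float) -> Bump:
    return Bump(
        onset=t0 + o["first_bin"] * window,
        offset=t0 + (o["last_bin"] + 1) * window,
        center=o["csum"] / max(o["mass"], 1),
        width=o["wsum"] / o["wn"],
        mass=int(o["mass"]),
    )


def decode_sequence(
    raster: SpikeRaster,
    item_regions: dict[str, tuple[int, int]],
    content_range: tuple[int, int],
    epochs: list[tuple[float, float]] | None = None,
    window: float = 100.0,
    rate_threshold: float = 40.0,
    confidence_threshold: float = 0.5,
    merge_gap: float = 700.0,
) -> DecodedSequence:
    """Decode the item sequence expressed by content-field bumps.

    With ``epochs`` given (e.g. the CoS-delimited replay windows), the
    dominant bump of each epoch yields one decoded item per epoch, with
    ``bump=None`` for epochs without any bump.  Without epochs, bumps
    are ordered by onset and consecutive same-label bumps closer than
    ``merge_gap`` ms are merged (a transition gap shorter than that does
    not constitute a new item).  Bumps whose confidence — the fraction
    of spike mass inside the best item region — falls below the
    threshold are flagged unassigned.
    """
    regions = sorted(item_regions.items(), key=lambda kv: kv[1][0])
    for (la, (a0, a1)), (lb, (b0, b1)) in zip(regions, regions[1:]):
        if b0 < a1:
            raise ConfigurationError(
                f"item regions {la} and {lb} overlap: ({a0},{a1}) ({b0},{b1})"
            )

    def classify(bump: Bump, t0: float, t1: float) -> DecodedItem:
        spikes = raster.window(max(t0, bump.onset), min(t1, bump.offset))
        best_label, best_mass = None, 0
        total = 0
        for lab, (lo, hi) in item_regions.items():
            m = int(((spikes.indices >= lo) & (spikes.indices < hi)).sum())
            total += m
            if m > best_mass:
                best_label, best_mass = lab, m
        in_field = int(((spikes.indices >= content_range[0])
                        & (spikes.indices < content_range[1])).sum())
        conf = best_mass / in_field if in_field else 0.0
        if conf < confidence_threshold:
            return DecodedItem(label=None, bump=bump, confidence=conf)
        return DecodedItem(label=best_label, bump=bump, confidence=conf)

    out = DecodedSequence()
    if epochs is not None:
        for (t0, t1) in epochs:
            bumps = detect_bumps(raster, content_range, window=window,
                                 rate_threshold=rate_threshold, t0=t0, t1=t1)
            if not bumps:
                out.items.append(DecodedItem(label=None, bump=None))
                continue
            bump = max(bumps, key=lambda bp: bp.mass)
            out.items.append(classify(bump, t0, t1))
        return out

    bumps = detect_bumps(raster, content_range, window=window,
                         rate_threshold=rate_threshold)
    for bump in bumps:
        item = classify(bump, bump.onset, bump.offset)
        if (out.items
                and out.items[-1].label == item.label
                and item.label is not None
                and out.items[-1].bump is not None
                and bump.onset - out.items[-1].bump.offset < merge_gap):
            prev = out.items[-1].bump
            prev.offset = bump.offset
            prev.mass += bump.mass
            continue
        out.items.append(item)
    return out


def score_probe(
    probe: np.ndarray,
    layout,
    item_regions: dict[str, tuple[int, int]],
) -> ProbeScore:
    """Fraction of potentiated entries per (ordinal group, item) block.

    ``winners[group]`` is the item whose block has the highest
    potentiated fraction (None if all blocks are empty);
    ``off_block_noise`` is the potentiated fraction of the
    ordinal→content area outside every (group, item) block.
    """
    probe = np.asarray(probe)
    groups = layout.group_names("ordinal")
    c_lo, c_hi = layout.range_of("content_exc")
    if probe.shape[0] < c_hi or probe.shape[1] < c_hi:
        raise ConfigurationError("probe matrix smaller than the layout")
    fractions: dict[tuple[str, str], float] = {}
    winners: dict[str, str | None] = {}
    in_block = np.zeros_like(probe, dtype=bool)
    for g in groups:
        g_lo, g_hi = layout.range_of(g)
        best, best_f = None, 0.0
        for lab, (r_lo, r_hi) in item_regions.items():
            block = probe[g_lo:g_hi, r_lo:r_hi]
            f = float(block.mean()) if block.size else 0.0
            fractions[(g, lab)] = f
            in_block[g_lo:g_hi, r_lo:r_hi] = True
            if f > best_f:
                best, best_f = lab, f
        winners[g] = best
    o_lo, o_hi = layout.span_of("ordinal")
    area = np.zeros_like(probe, dtype=bool)
    area[o_lo:o_hi, c_lo:c_hi] = True
    off = area & ~in_block
    off_noise = float(probe[off].mean()) if off.any() else 0.0
    return ProbeScore(block_fractions=fractions, off_block_noise=off_noise,
                      winners=winners)


def plot_raster(raster: SpikeRaster, layout=None, ax=None, **scatter_kw):
    """Raster plot with populations colour-banded (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 6))
    ax.scatter(raster.times / 1000.0, raster.indices, s=1, c="k",
               **scatter_kw)
    if layout is not None:
        cmap = plt.get_cmap("tab10")
        for i, (name, (lo, hi)) in enumerate(layout.ranges.items()):
            ax.axhspan(lo, hi, color=cmap(i % 10), alpha=0.12)
            ax.text(0.0, (lo + hi) / 2, name, fontsize=7, va="center")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("neuron index")
    return ax
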