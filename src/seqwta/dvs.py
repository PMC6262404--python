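"""Synthetic event-camera (DVS/AER) front end.

A dynamic vision sensor emits address events ``(t, x, y, polarity)``
whenever a pixel's brightness changes.  The generator here emulates the
classic bench stimulus: a blinking laser pointer highlighting columns of
the scene, producing a burst of events around the lit column plus
uniform background noise.  Events map onto the content field by linear
binning of the x coordinate (polarity is ignored), and every event also
drives the ``dvs_on`` population, which inhibits the CoS group — so the
CoS fires (and the sequence steps forward) exactly when the laser turns
off while the content field is still active.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .builder import PopulationLayout
from .errors import ConfigurationError

__all__ = [
    "AEREvent",
    "LaserScript",
    "synth_dvs_stream",
    "dvs_to_content",
    "events_to_drive",
    "write_events_csv",
    "read_events_csv",
]

SENSOR_RESOLUTION = (128, 128)


@dataclass(frozen=True)
class AEREvent:
    """One address event: time (ms), pixel coordinates, polarity (±1)."""

    t: float
    x: int
    y: int
    polarity: int = 1


@dataclass(frozen=True)
class LaserScript:
    """Blinking-laser schedule: per step a lit column and on/off times."""

    steps: tuple[tuple[int, float, float], ...]  # (x_column, on_ms, off_ms)
    on_event_rate: float = 5000.0  # events/s while lit
    noise_event_rate: float = 100.0  # background events/s over the sensor
    jitter_sigma: float = 1.5  # pixel scatter around the lit column

    def __post_init__(self) -> None:
        for x, on, off in self.steps:
            if on <= 0 or off <= 0:
                raise ConfigurationError("laser on/off durations must be > 0")


def synth_dvs_stream(
    script: LaserScript,
    duration: float,
    seed: int = 0,
    resolution: tuple[int, int] = SENSOR_RESOLUTION,
) -> list[AEREvent]:
    """Generate a time-ordered synthetic event stream.

    While the laser is on at column x, events arrive as a Poisson
    process at ``on_event_rate`` with columns scattered around x by
    Gaussian jitter (clipped to the sensor); off periods and the rest of
    the run emit only background noise, uniform over all pixels at
    ``noise_event_rate``.  Polarities are random — downstream processing
    ignores them anyway.
    """
    rx, ry = resolution
    rng = np.random.default_rng(seed)
    times: list[np.ndarray] = []
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []

    t = 0.0
    for x_col, on_ms, off_ms in script.steps:
        if t >= duration:
            break
        if not (0 <= x_col < rx):
            raise ConfigurationError(f"laser column {x_col} outside sensor")
        t_on_end = min(t + on_ms, duration)
        n = rng.poisson(script.on_event_rate * (t_on_end - t) * 1e-3)
        ev_t = rng.uniform(t, t_on_end, size=n)
        ev_x = np.clip(
            np.rint(x_col + rng.normal(0, script.jitter_sigma, size=n)),
            0, rx - 1,
        ).astype(int)
        times.append(ev_t)
        xs.append(ev_x)
        ys.append(rng.integers(0, ry, size=n))
        t = t_on_end + off_ms
    # background noise over the whole run
    n = rng.poisson(script.noise_event_rate * duration * 1e-3)
    times.append(rng.uniform(0, duration, size=n))
    xs.append(rng.integers(0, rx, size=n))
    ys.append(rng.integers(0, ry, size=n))

    all_t = np.concatenate(times)
    all_x = np.concatenate(xs)
    all_y = np.concatenate(ys)
    order = np.argsort(all_t, kind="stable")
    pol = rng.choice((-1, 1), size=all_t.size)
    return [
        AEREvent(float(all_t[i]), int(all_x[i]), int(all_y[i]), int(pol[i]))
        for i in order
    ]


def dvs_to_content(
    x: int,
    layout: PopulationLayout,
    resolution: tuple[int, int] = SENSOR_RESOLUTION,
) -> int:
    """Linear binning of a pixel column onto a content-field neuron."""
    rx = resolution[0]
    if not (0 <= x < rx):
        raise ConfigurationError(f"x={x} outside sensor width {rx}")
    c_lo, c_hi = layout.range_of("content_exc")
    n = c_hi - c_lo
    return c_lo + min(int(x * n / rx), n - 1)


def events_to_drive(
    events: list[AEREvent],
    layout: PopulationLayout,
    dt: float,
    content_weight: float = 0.5,
    dvs_on_weight: float = 0.2,
    resolution: tuple[int, int] = SENSOR_RESOLUTION,
) -> tuple[tuple[np.ndarray, np.ndarray, np.ndarray], int]:
    """Convert events into the kernel's event-driven input arrays.

    Every in-bounds event stimulates its content neuron (by x column,
    polarity ignored) and, spread uniformly, the ``dvs_on`` population.
    Events outside the sensor bounds are rejected and counted.  Returns
    ``((step, neuron, amount), n_rejected)`` sorted by step.
    """
    if "dvs_on" not in layout:
        raise ConfigurationError("layout has no dvs_on population")
    d_lo, d_hi = layout.range_of("dvs_on")
    rx, ry = resolution
    steps: list[int] = []
    neurons: list[int] = []
    amounts: list[float] = []
    rejected = 0
    for k, ev in enumerate(events):
        if not (0 <= ev.x < rx and 0 <= ev.y < ry):
            rejected += 1
            continue
        step = int(ev.t / dt)
        steps.append(step)
        neurons.append(dvs_to_content(ev.x, layout, resolution))
        amounts.append(content_weight)
        steps.append(step)
        neurons.append(d_lo + k % (d_hi - d_lo))
        amounts.append(dvs_on_weight)
    order = np.argsort(np.asarray(steps, dtype=np.int64), kind="stable")
    return (
        (
            np.asarray(steps, dtype=np.int64)[order],
            np.asarray(neurons, dtype=np.int64)[order],
            np.asarray(amounts)[order],
        ),
        rejected,
    )


def write_events_csv(events: list[AEREvent], path) -> None:
    """CSV with columns (t_ms, x, y, pol)."""
    with open(path, "w") as fh:
        fh.write("t_ms,x,y,pol\n")
        for ev in events:
            fh.write(f"{float(ev.t)!r},{ev.x},{ev.y},{ev.polarity}\n")


def read_events_csv(path) -> list[AEREvent]:
    events = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "t_ms,x,y,pol":
            raise ConfigurationError(f"{path}: not an AER event CSV")
        for ln, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            try:
                t, x, y, pol = line.split(",")
                events.append(AEREvent(float(t), int(x), int(y), int(pol)))
            except ValueError as e:
                raise ConfigurationError(f"{path}:{ln}: bad event row") from e
    return events
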