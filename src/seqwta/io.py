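"""File formats: rasters, matrices, configs, run manifests.

Everything round-trips losslessly.  Rasters are two-column text
(``time_ms neuron_index``) with a small header, or an ``.npz`` binary
container; matrices are CSV with a JSON layout sidecar; configs are
YAML; manifests are JSON recording the config hash, seed, and package
version, so a result file is traceable to the exact run that made it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from .builder import PopulationLayout
from .errors import ConfigurationError
from .network import SpikeRaster

__all__ = [
    "write_raster", "read_raster",
    "write_raster_npz", "read_raster_npz",
    "write_matrix", "read_matrix",
    "write_matrix_npy", "read_matrix_npy",
    "write_config", "read_config",
    "config_hash", "write_manifest", "read_manifest",
]

_RASTER_MAGIC = "# seqwta-raster v1"


def write_raster(raster: SpikeRaster, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{_RASTER_MAGIC}\n")
        fh.write(f"# n_neurons={raster.n_neurons} "
                 f"duration_ms={raster.duration!r}\n")
        for t, i in zip(raster.times, raster.indices):
            fh.write(f"{float(t)!r} {int(i)}\n")


def read_raster(path) -> SpikeRaster:
    with open(path) as fh:
        magic = fh.readline().strip()
        if magic != _RASTER_MAGIC:
            raise ConfigurationError(f"{path}:1: not a seqwta raster file")
        meta = fh.readline().strip()
        try:
            fields = dict(kv.split("=") for kv in meta.lstrip("# ").split())
            n_neurons = int(fields["n_neurons"])
            duration = float(fields["duration_ms"])
        except (ValueError, KeyError) as e:
            raise ConfigurationError(f"{path}:2: bad raster header") from e
        times, idx = [], []
        for ln, line in enumerate(fh, start=3):
            line = line.strip()
            if not line:
                continue
            try:
                t, i = line.split()
                times.append(float(t))
                idx.append(int(i))
            except ValueError as e:
                raise ConfigurationError(f"{path}:{ln}: bad raster row") from e
    return SpikeRaster(np.asarray(times), np.asarray(idx, dtype=np.int64),
                       n_neurons, duration)


def write_raster_npz(raster: SpikeRaster, path) -> None:
    np.savez_compressed(path, times=raster.times, indices=raster.indices,
                        n_neurons=raster.n_neurons, duration=raster.duration)


def read_raster_npz(path) -> SpikeRaster:
    with np.load(path) as d:
        return SpikeRaster(d["times"], d["indices"], int(d["n_neurons"]),
                           float(d["duration"]))


def write_matrix(weights: np.ndarray, path,
                 layout: PopulationLayout | None = None) -> None:
    """Dense signed matrix as CSV; layout sidecar ``<path>.layout.json``."""
    np.savetxt(path, np.asarray(weights), delimiter=",", fmt="%.12g")
    if layout is not None:
        sidecar = Path(str(path) + ".layout.json")
        sidecar.write_text(json.dumps(layout.to_dict(), indent=1))


def read_matrix(path) -> tuple[np.ndarray, PopulationLayout | None]:
    try:
        w = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError as e:
        raise ConfigurationError(f"{path}: malformed matrix CSV: {e}") from e
    sidecar = Path(str(path) + ".layout.json")
    layout = None
    if sidecar.exists():
        layout = PopulationLayout.from_dict(json.loads(sidecar.read_text()))
    return w, layout


def write_matrix_npy(weights: np.ndarray, path) -> None:
    np.save(path, np.asarray(weights))


def read_matrix_npy(path) -> np.ndarray:
    return np.load(path)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def write_config(config, path) -> None:
    """Any (nested) dataclass or dict, as YAML."""
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=True))


def read_config(path) -> dict:
    try:
        out = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as e:
        raise ConfigurationError(f"{path}: bad YAML: {e}") from e
    if not isinstance(out, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return out


def config_hash(config) -> str:
    canon = yaml.safe_dump(_to_plain(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_manifest(path, config, seed: int, extra: dict | None = None) -> None:
    from . import __version__

    manifest = {
        "config_hash": config_hash(config),
        "seed": int(seed),
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))


def read_manifest(path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ConfigurationError(f"{path}: bad manifest JSON: {e}") from e
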