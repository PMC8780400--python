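"""Run configuration: YAML/JSON parsing, hashing and object construction.

A run configuration is a plain nested mapping with sections ``geometry``,
``params``, ``connectivity``, ``stimulus``, ``integrator`` and ``output``.
The configuration hash is computed over the canonical (sorted-key) JSON
serialisation, so key order never changes the hash, and every exported
artifact carries the hash of the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .core import ConnectivityMatrices, LayerGeometry, RetinaParams
from .stimuli import (
    ChirpSweep,
    FullFieldFlash,
    MovingBar,
    PeriodicFlashes,
    make_dog_kernel,
)

__all__ = [
    "load_config",
    "dump_config",
    "config_hash",
    "derive_seed",
    "build_geometry",
    "build_params",
    "build_connectivity",
    "build_stimulus",
    "build_kernels",
]

_STIMULI = {
    "flash": FullFieldFlash,
    "periodic_flashes": PeriodicFlashes,
    "chirp_sweep": ChirpSweep,
    "moving_bar": MovingBar,
}


def load_config(path) -> dict:
    """Load a YAML (or JSON) configuration file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def dump_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def _canonical(obj):
    if isinstance(obj, dict):
        return {str(k): _canonical(v) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def config_hash(cfg: dict) -> str:
    """Stable hex digest of a configuration (key order irrelevant)."""
    blob = json.dumps(_canonical(cfg), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def derive_seed(master_seed: int, stream: str) -> int:
    """Deterministic per-component seed derived from the master seed.

    Hash-based derivation keeps streams independent, so adding a new
    consumer never perturbs existing ones.  Result is < 2**31.
    """
    h = hashlib.sha256(f"{master_seed}:{stream}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def build_geometry(section: dict) -> LayerGeometry:
    return LayerGeometry(
        edge_mm=float(section["edge_mm"]),
        spacing_mm={k: float(v) for k, v in section["spacing_mm"].items()},
    )


def build_params(section: dict) -> RetinaParams:
    return RetinaParams(**section)


def build_connectivity(section: dict, geometry: LayerGeometry) -> ConnectivityMatrices:
    """Connectivity from a generator spec or explicit CSV matrices."""
    from .fixtures import generate_pooling_connectivity

    kind = section.get("generator", "pooling")
    if kind == "pooling":
        kwargs = {k: v for k, v in section.items() if k != "generator"}
        return generate_pooling_connectivity(geometry, **kwargs)
    if kind == "explicit":
        mats = {
            key: np.loadtxt(section[key], delimiter=",", ndmin=2)
            for key in ("w_ba", "w_ab", "w_gb", "w_ga")
        }
        return ConnectivityMatrices(**mats)
    raise ValueError(f"unknown connectivity generator {kind!r}")


def build_stimulus(section: dict):
    kind = section["type"]
    if kind not in _STIMULI:
        raise ValueError(f"unknown stimulus type {kind!r}")
    kwargs = {k: v for k, v in section.items() if k != "type"}
    return _STIMULI[kind](**kwargs)


def build_kernels(section: dict, geometry: LayerGeometry):
    """One receptive-field kernel per bipolar cell, centred on its lattice
    site, from a shared kernel spec."""
    coords = geometry.coordinates("B")
    return [
        make_dog_kernel(center=(x, y), **section) for x, y in coords
    ]
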