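"""Result writers: HDF5 bundles, CSV tables and payload hashing.

Every numeric artifact is written together with the metadata needed to
reproduce it: configuration hash, seeds, tolerances and the package
version.  ``payload_hash`` digests only the numeric payload (not
timestamps or attribute order), so reproducibility can be asserted as
hash equality.
"""

from __future__ import annotations

import hashlib

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .dynamics import Trajectory
from .gif import SpikeRaster

__all__ = [
    "save_trajectory",
    "load_trajectory",
    "save_events_csv",
    "save_kernel",
    "save_covariance",
    "save_raster",
    "payload_hash",
]


def _write_meta(group, meta: dict | None) -> None:
    group.attrs["tool_version"] = __version__
    for key, value in (meta or {}).items():
        if value is None:
            continue
        group.attrs[key] = value


def save_trajectory(path, traj: Trajectory, meta: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=traj.ts)
        f.create_dataset("states", data=traj.xs)
        ev = np.array(
            [(t, cb, ca) for (t, cb, ca, _) in traj.events], dtype=float
        ).reshape(-1, 3)
        f.create_dataset("events", data=ev)
        f.attrs["nb"] = traj.nb
        f.attrs["na"] = traj.na
        f.attrs["ng"] = traj.ng
        f.attrs["extended"] = traj.extended
        _write_meta(f, {**traj.meta, **(meta or {})})


def load_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as f:
        return Trajectory(
            ts=f["times"][:],
            xs=f["states"][:],
            events=[(row[0], int(row[1]), int(row[2]), None) for row in f["events"][:]],
            segments=[],
            nb=int(f.attrs["nb"]),
            na=int(f.attrs["na"]),
            ng=int(f.attrs["ng"]),
            extended=bool(f.attrs["extended"]),
            meta={k: f.attrs[k] for k in f.attrs},
        )


def save_events_csv(path, traj: Trajectory) -> None:
    df = pd.DataFrame(
        [(t, cb, ca) for (t, cb, ca, _) in traj.events],
        columns=["time_ms", "domain_from", "domain_to"],
    )
    df.to_csv(path, index=False)


def save_kernel(path, kernel, xs, ys, meta: dict | None = None) -> None:
    """Write an assembled receptive-field kernel sampled on a grid."""
    arr = kernel.sample(xs, ys)
    with h5py.File(path, "w") as f:
        f.create_dataset("x_mm", data=np.asarray(xs))
        f.create_dataset("y_mm", data=np.asarray(ys))
        f.create_dataset("t_ms", data=kernel.ts)
        f.create_dataset("kernel", data=arr)
        f.create_dataset("temporal_mix", data=kernel.temporal_mix)
        f.attrs["cell_index"] = kernel.cell_index
        f.attrs["imag_residue"] = kernel.imag_residue
        _write_meta(f, meta)


def save_covariance(path, cov, meta: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("sigma", data=cov.sigma)
        f.create_dataset("L", data=cov.L)
        f.attrs["sigma_s"] = cov.sigma_s
        f.attrs["lag_convention"] = "C(t,t') = Cov(X(t), X(t')), t' >= t"
        _write_meta(f, meta)


def save_raster(path, raster: SpikeRaster, meta: dict | None = None) -> None:
    """Dense HDF5 raster plus (trial, neuron, bin) event list CSV when the
    path ends in .csv."""
    if str(path).endswith(".csv"):
        tr, nrn, bins = np.nonzero(raster.data)
        pd.DataFrame({"trial": tr, "neuron": nrn, "bin": bins}).to_csv(
            path, index=False
        )
        return
    with h5py.File(path, "w") as f:
        f.create_dataset("spikes", data=raster.data.astype(np.uint8),
                         compression="gzip")
        f.attrs["bin_ms"] = raster.dt
        if raster.seed is not None:
            f.attrs["seed"] = raster.seed
        _write_meta(f, {**raster.meta, **(meta or {})})


def payload_hash(*arrays) -> str:
    """Hex digest of the numeric payload of one or more arrays."""
    h = hashlib.sha256()
    for a in arrays:
        a = np.ascontiguousarray(a)
        h.update(str(a.dtype).encode())
        h.update(str(a.shape).encode())
        h.update(a.tobytes())
    return h.hexdigest()[:16]
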