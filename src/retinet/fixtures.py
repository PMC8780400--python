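"""Reproducible synthetic networks emulating the modelled retinal circuits.

Two families are provided: lattice networks with local Gaussian pooling
(B -> G), nearest-neighbour B <-> A coupling and A -> G inhibition, used
by the receptive-field and correlation analyses; and small random signed
networks rescaled to a stable rest operator, used for property testing.
The defaults describe a sub-millimetre patch with bipolar cells at 25 um
pitch pooled by ganglion cells over ~50 um, lateral inhibition one
lattice step wide — a caricature of the inner retina's local circuitry,
not a fit to any species.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .core import ConnectivityMatrices, LayerGeometry, RetinaParams
from .dynamics import DomainIndex, build_transport_operator

__all__ = [
    "generate_pooling_connectivity",
    "random_stable_network",
    "default_geometry",
    "chain_experiment_defaults",
]


def default_geometry(edge_mm: float = 0.1, nb_row: int = 4, na_row: int = 2,
                     ng_row: int = 2) -> LayerGeometry:
    return LayerGeometry(
        edge_mm=edge_mm,
        spacing_mm={
            "B": edge_mm / nb_row,
            "A": edge_mm / na_row,
            "G": edge_mm / ng_row,
        },
    )


def generate_pooling_connectivity(
    geometry: LayerGeometry,
    pooling_radius: float = 0.05,
    w_gb: float = 1.0,
    w_ab: float = 0.5,
    w_ba: float = 0.5,
    w_ga: float = 0.25,
    neighbor_radius: float | None = None,
    jitter: float = 0.0,
    seed: int | None = None,
) -> ConnectivityMatrices:
    """Local pooling connectivity on the layered lattice.

    Ganglion cells pool bipolar cells with Gaussian weights of scale
    ``pooling_radius`` (mm); a vanishing radius degenerates to one-to-one
    pooling of the nearest bipolar cell.  B <-> A coupling connects cells
    within ``neighbor_radius`` (default: one step of the coarser of the
    two lattices), with the mandatory signs (A -> B inhibitory).  A -> G
    inhibition pools like B -> G.  ``jitter`` multiplies every weight by
    ``1 + jitter * U(-1, 1)`` with a seeded generator, so the result is
    deterministic given the seed.  Coordinates, not indices, are mapped,
    so the per-layer lattice densities may differ.
    """
    rng = np.random.default_rng(seed)
    cb = geometry.coordinates("B")
    ca = geometry.coordinates("A")
    cg = geometry.coordinates("G")
    d_gb = cdist(cg, cb)
    d_ga = cdist(cg, ca)
    d_ab = cdist(ca, cb)

    def pool(dist, scale):
        if pooling_radius <= 1e-9:
            out = np.zeros_like(dist)
            out[np.arange(dist.shape[0]), np.argmin(dist, axis=1)] = scale
            return out
        return scale * np.exp(-(dist**2) / (2 * pooling_radius**2))

    wgb = pool(d_gb, w_gb)
    wga = -pool(d_ga, w_ga)
    if neighbor_radius is None:
        neighbor_radius = 1.01 * max(geometry.spacing_mm["B"], geometry.spacing_mm["A"])
    near = d_ab <= neighbor_radius
    wab = w_ab * near.astype(float)
    wba = -w_ba * near.T.astype(float)

    def jit(mat, sign):
        if jitter <= 0:
            return mat
        factor = 1.0 + jitter * rng.uniform(-1, 1, size=mat.shape)
        return mat * factor

    return ConnectivityMatrices(
        w_ba=jit(wba, -1), w_ab=jit(wab, 1), w_gb=jit(wgb, 1), w_ga=jit(wga, -1)
    )


def random_stable_network(
    nb: int = 4,
    na: int = 2,
    ng: int = 2,
    seed: int = 0,
    coupling: float = 0.5,
    params: RetinaParams | None = None,
    max_rescale: int = 30,
) -> tuple[RetinaParams, ConnectivityMatrices]:
    """Random signed network rescaled until the rest operator is stable.

    Weights are drawn half-normal with the mandated signs; if the
    non-rectified transport operator is unstable the lateral coupling is
    halved (up to ``max_rescale`` times).  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    if params is None:
        params = RetinaParams(
            tau_b=float(rng.uniform(8, 15)),
            tau_a=float(rng.uniform(8, 15)),
            tau_g=float(rng.uniform(4, 8)),
        )
    w_ab0 = np.abs(rng.normal(size=(na, nb)))
    w_ba0 = -np.abs(rng.normal(size=(nb, na)))
    w_gb = np.abs(rng.normal(size=(ng, nb)))
    w_ga = -np.abs(rng.normal(size=(ng, na)))
    c = coupling
    for _ in range(max_rescale):
        conn = ConnectivityMatrices(
            w_ba=c * w_ba0, w_ab=c * w_ab0, w_gb=w_gb, w_ga=w_ga
        )
        dom0 = DomainIndex(eta=(0,) * (nb + na))
        op = build_transport_operator(dom0, params, conn)
        if op.is_stable():
            return params, conn
        c *= 0.5
    raise RuntimeError("could not stabilise the random network")


def chain_experiment_defaults() -> dict:
    """Documented parameter set for the spiking-chain experiment.

    Chosen by the implementers to yield asynchronous spontaneous activity
    (noise-driven, no pacemaking) with spontaneous rates of a few hertz
    per 1 ms bin fraction, nearest-neighbour excitation and
    second-nearest inhibition weak enough to keep the network in the
    fluctuation-driven regime.  No claim is made of matching any
    published tuning.
    """
    return {
        "n": 20,
        "w_exc": 0.02,
        "w_inh": 0.3,
        "e_exc": 2.0,
        "e_inh": -3.0,
        "tau_syn": 5.0,
        "profile": "exp",
        "gif": {
            "cap": 1.0,
            "g_leak": 0.1,
            "e_leak": 0.0,
            "theta": 1.0,
            "v_reset": 0.0,
            "sigma_noise": 0.24,
            "dt": 0.1,
        },
        "bump": {"speed": 0.03, "width": 0.8},
        "bump_amplitude": 0.35,
        "weak_amplitude": 0.04,
    }
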