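"""Shared fixtures: small networks, kernels and drive grids.

Everything is generated programmatically and deterministically; no data
files are read.
"""

import numpy as np
import pytest

from retinet import ConnectivityMatrices, RetinaParams
from retinet.config import build_kernels
from retinet.fixtures import default_geometry, generate_pooling_connectivity, random_stable_network
from retinet.stimuli import DriveForcing, FullFieldFlash, compute_drive, make_dog_kernel


@pytest.fixture(scope="session")
def small_network():
    """4+2+2 random stable network with mixed (nonzero) thresholds."""
    params0, conn = random_stable_network(4, 2, 2, seed=1)
    params = RetinaParams(
        tau_b=params0.tau_b, tau_a=params0.tau_a, tau_g=params0.tau_g,
        theta_b=0.1, theta_a=-0.05,
    )
    return params, conn


@pytest.fixture(scope="session")
def flash_forcing(small_network):
    """Piecewise-linear forcing from a full-field flash through a DoG kernel."""
    params, conn = small_network
    kern = make_dog_kernel(0.02, 0.04, center=(0.0, 0.0))
    ts = np.arange(0.0, 300.001, 0.1)
    stim = FullFieldFlash(contrast=1.0, t_on=10, t_off=60, ramp=5)
    d = compute_drive(kern, stim, ts)
    drives = np.array([d * (1 + 0.2 * i) for i in range(conn.nb)])
    tau_b, _, _ = params.tau_vectors(conn.nb, conn.na, conn.ng)
    return DriveForcing(ts, drives, tau_b, conn.n_total)


@pytest.fixture(scope="session")
def lattice_network():
    """9+4+4 lattice network with weak lateral loop: certified linear
    regime fixture (zero thresholds, background keeps the operating point
    inside the rest domain)."""
    geom = default_geometry(edge_mm=0.1, nb_row=3, na_row=2, ng_row=2)
    conn = generate_pooling_connectivity(
        geom, pooling_radius=0.03, w_ab=0.03, w_ba=0.03, jitter=0.3, seed=2
    )
    params = RetinaParams(tau_b=12.0, tau_a=9.0, tau_g=6.0)
    kernels = build_kernels(
        {"sigma_center": 0.015, "sigma_surround": 0.03, "w_surround": 0.3}, geom
    )
    return geom, params, conn, kernels


@pytest.fixture(scope="session")
def oscillator_network():
    """1 B + 1 A strongly coupled (complex eigenpair) with a G readout."""
    w = 2.0
    conn = ConnectivityMatrices(
        w_ba=[[-w]], w_ab=[[w]], w_gb=[[1.0]], w_ga=[[0.0]]
    )
    params = RetinaParams(tau_b=20.0, tau_a=20.0, tau_g=5.0)
    return params, conn
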