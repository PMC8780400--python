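"""Eigen-analysis of the rest-domain operator and closed-form responses.

In the non-rectified regime the network response is a convolution: the
deviation of the state from rest is a sum over eigenmodes of the rest
transport operator, each mode filtering the bipolar drives with its
complex decay rate.  Identifying terms yields an explicit space-time
receptive-field kernel for every cell — ganglion-cell kernels inherit the
bipolar kernels reshaped by the lateral (amacrine) connectivity, which in
general breaks space-time separability and can create temporal resonances
through complex eigenvalue pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dynamics import TransportOperator
from .stimuli import SpatioTemporalKernel, exp_filter_pl

__all__ = [
    "SpectralDecomposition",
    "RGKernel",
    "decompose",
    "closed_form_response",
    "rg_kernel",
    "separability_index",
    "resonance_scan",
    "certify_weak_amplitude",
]


@dataclass
class SpectralDecomposition:
    """Eigenvalues and right/left eigenvectors of a transport operator."""

    L: np.ndarray
    eigenvalues: np.ndarray
    P: np.ndarray
    Pinv: np.ndarray
    stable: bool
    diagonalizable: bool
    min_gap: float

    def reconstruction_error(self) -> float:
        rec = (self.P * self.eigenvalues[None, :]) @ self.Pinv
        scale = max(np.abs(self.L).max(), 1e-300)
        return float(np.abs(rec - self.L).max() / scale)


def decompose(op, degeneracy_tol: float = 1e-8) -> SpectralDecomposition:
    """Full eigen-decomposition of a transport operator (or raw matrix).

    Near-degenerate eigenvalues (gap below ``degeneracy_tol``) flag the
    decomposition as unsuitable for spectral assembly — the eigenvector
    matrix is then ill-conditioned or defective and exponential-based
    propagation must be used instead.
    """
    L = op.L if isinstance(op, TransportOperator) else np.asarray(op, dtype=float)
    lam, P = np.linalg.eig(L)
    Pinv = np.linalg.inv(P)
    gaps = np.abs(lam[:, None] - lam[None, :])
    np.fill_diagonal(gaps, np.inf)
    min_gap = float(gaps.min()) if L.shape[0] > 1 else np.inf
    decomp = SpectralDecomposition(
        L=L,
        eigenvalues=lam,
        P=P,
        Pinv=Pinv,
        stable=bool(np.all(lam.real < 0)),
        diagonalizable=True,
        min_gap=min_gap,
    )
    # exactly repeated eigenvalues are common (e.g. uncoupled ganglion
    # cells sharing a time constant) and harmless while the eigenbasis is
    # well conditioned; defectiveness shows up as an ill-conditioned P or
    # a failed reconstruction, which is what is tested here.
    if (
        decomp.reconstruction_error() > 1e-8
        or np.linalg.cond(P) > 1.0 / degeneracy_tol
    ):
        decomp.diagonalizable = False
    return decomp


def _require_spectral(decomp: SpectralDecomposition) -> None:
    if not decomp.diagonalizable:
        raise ValueError(
            "operator is defective or near-degenerate "
            f"(min eigenvalue gap {decomp.min_gap:.3g}); "
            "use the exponential-based (non-spectral) path"
        )


def closed_form_response(
    decomp: SpectralDecomposition,
    ts: np.ndarray,
    drives: np.ndarray,
    tau_b,
) -> np.ndarray:
    """Network response to bipolar drives in the non-rectified regime.

    Returns the deviation of every cell's voltage from the rest state,
    sampled on the uniform grid ``ts``:

    ``X_a(t) = Vdrive_a(t)
             + sum_bg P[a,b] Pinv[b,g] (lam_b + 1/tau_Bg)
               int exp(lam_b (t-s)) Vdrive_g(s) ds``

    with the drive term present only on B rows.  The mode weight
    ``lam_b + 1/tau_Bg`` arises from integrating the drive-derivative
    part of the forcing by parts.  Drives are treated as piecewise-linear
    on ``ts`` (zero before the first sample), consistently with
    :class:`~retinet.stimuli.DriveForcing`.
    """
    _require_spectral(decomp)
    if not decomp.stable:
        raise ValueError("unstable spectrum: stationary convolution form invalid")
    ts = np.asarray(ts, dtype=float)
    drives = np.atleast_2d(np.asarray(drives, dtype=float))
    nb, nt = drives.shape
    n = decomp.L.shape[0]
    tau_b = np.broadcast_to(np.asarray(tau_b, dtype=float), (nb,))
    lam = decomp.eigenvalues
    net = np.zeros((n, nt), dtype=complex)
    for b in range(n):
        acc = np.zeros(nt, dtype=complex)
        for g in range(nb):
            w = decomp.Pinv[b, g] * (lam[b] + 1.0 / tau_b[g])
            if w == 0:
                continue
            acc += w * exp_filter_pl(lam[b], ts, drives[g])
        net[b] = acc
    resp = decomp.P @ net
    resid = np.abs(resp.imag).max()
    scale = max(np.abs(resp.real).max(), 1e-300)
    if resid > 1e-8 * scale:
        warnings.warn(f"imaginary residue {resid:.3g} in closed-form response",
                      stacklevel=2)
    out = resp.real.copy()
    out[:nb] += drives
    return out.T  # (nt, n)


@dataclass
class RGKernel:
    """Receptive-field kernel of one cell, assembled from network modes.

    The kernel is a sum over bipolar cells ``g`` of (spatial part of the
    bipolar kernel g) x (mode-filtered temporal part): assembling it on a
    grid is ``K(x, y, t) = sum_g KS_g(x - x_g, y - y_g) T_g(t)``.
    """

    cell_index: int
    ts: np.ndarray
    temporal_mix: np.ndarray  # (NB, nt) real
    b_kernels: list[SpatioTemporalKernel] = field(repr=False)
    imag_residue: float = 0.0

    def sample(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        """Sample the kernel on a space-time grid: (nx, ny, nt)."""
        xs = np.asarray(xs, dtype=float)
        ys = np.asarray(ys, dtype=float)
        out = np.zeros((len(xs), len(ys), len(self.ts)))
        for g, kern in enumerate(self.b_kernels):
            xc, yc = kern.center
            sp = kern.spatial(xs[:, None] - xc, ys[None, :] - yc)
            out += sp[:, :, None] * self.temporal_mix[g][None, None, :]
        return out

    def fullfield_temporal(self) -> np.ndarray:
        """Effective temporal kernel for full-field stimuli: each bipolar
        spatial part integrates to its total mass."""
        masses = np.array([k.spatial_integral for k in self.b_kernels])
        return masses @ self.temporal_mix

    def predict_fullfield(self, field_values: np.ndarray) -> np.ndarray:
        """Convolve the kernel with a full-field stimulus sampled on ts.

        Trapezoidal discrete convolution; returns the predicted voltage
        deviation on the same grid.
        """
        kt = self.fullfield_temporal()
        s = np.asarray(field_values, dtype=float)
        if len(s) != len(self.ts):
            raise ValueError("stimulus must be sampled on the kernel grid")
        dt = self.ts[1] - self.ts[0]
        full = np.convolve(kt, s)[: len(s)] * dt
        # trapezoid end-correction: the u=0 and u=t endpoints carry half weight
        return full - 0.5 * dt * (kt[0] * s + kt * s[0])


def rg_kernel(
    decomp: SpectralDecomposition,
    b_kernels: list[SpatioTemporalKernel],
    cell_index: int,
    tau_b,
    ts: np.ndarray,
) -> RGKernel:
    """Assemble the receptive-field kernel of cell ``cell_index``.

    ``K(x,y,t) = sum_bg P[a,b] Pinv[b,g] (lam_b + 1/tau_Bg)
                  (e_b *t K_Bg)(t)`` with ``e_b(t) = exp(lam_b t) H(t)``.
    Although aimed at ganglion cells, the same formula yields bipolar and
    amacrine receptive fields.  Complex modes come in conjugate pairs, so
    the assembled kernel is real up to numerical residue.
    """
    _require_spectral(decomp)
    if not decomp.stable:
        raise ValueError("unstable spectrum: kernel assembly invalid")
    ts = np.asarray(ts, dtype=float)
    nb = len(b_kernels)
    tau_b = np.broadcast_to(np.asarray(tau_b, dtype=float), (nb,))
    lam = decomp.eigenvalues
    n = decomp.L.shape[0]
    kt_samples = [k.temporal(ts) for k in b_kernels]
    mix = np.zeros((nb, len(ts)), dtype=complex)
    for b in range(n):
        pab = decomp.P[cell_index, b]
        if pab == 0:
            continue
        for g in range(nb):
            w = pab * decomp.Pinv[b, g] * (lam[b] + 1.0 / tau_b[g])
            if w == 0:
                continue
            mix[g] += w * exp_filter_pl(lam[b], ts, kt_samples[g])
    scale = max(np.abs(mix.real).max(), 1e-300)
    resid = float(np.abs(mix.imag).max() / scale)
    if resid > 1e-10:
        warnings.warn(f"imaginary residue {resid:.3g} in assembled kernel",
                      stacklevel=2)
    return RGKernel(
        cell_index=cell_index,
        ts=ts,
        temporal_mix=mix.real,
        b_kernels=list(b_kernels),
        imag_residue=resid,
    )


def separability_index(kernel, xs=None, ys=None) -> float:
    """Ratio sigma_2 / sigma_1 of the (space, time)-unfolded kernel.

    Zero iff the kernel factorises into (spatial) x (temporal).  Accepts
    an :class:`RGKernel` (sampled on ``xs``/``ys``, defaulting to a grid
    covering the bipolar centres) or a pre-sampled (nx, ny, nt) array.
    """
    if isinstance(kernel, RGKernel):
        if xs is None:
            centers = np.array([k.center for k in kernel.b_kernels])
            rad = max(k.spatial.support_radius for k in kernel.b_kernels)
            xs = np.linspace(centers[:, 0].min() - rad, centers[:, 0].max() + rad, 25)
            ys = np.linspace(centers[:, 1].min() - rad, centers[:, 1].max() + rad, 25)
        arr = kernel.sample(xs, ys)
    else:
        arr = np.asarray(kernel, dtype=float)
    mat = arr.reshape(-1, arr.shape[-1])
    s = np.linalg.svd(mat, compute_uv=False)
    if s[0] == 0:
        return 0.0
    return float(s[1] / s[0])


def certify_weak_amplitude(run_fn, amplitude: float, max_halvings: int = 12):
    """Scan the stimulus amplitude downward until no rectification occurs.

    ``run_fn(amplitude)`` must return a Trajectory; the first amplitude
    whose run produces no crossing events is certified and returned with
    its trajectory.
    """
    amp = float(amplitude)
    for _ in range(max_halvings + 1):
        traj = run_fn(amp)
        if traj.n_events == 0:
            return amp, traj
        amp /= 2.0
    raise RuntimeError("could not certify a non-rectifying amplitude")


def resonance_scan(
    run_fn,
    freqs,
    readout: int,
    settle_time: float,
    measure_time: float,
):
    """Steady-state amplitude of a cell's response to periodic flash trains.

    ``run_fn(freq, t_end)`` simulates the network under a flash train of
    the given frequency (cycles/ms) up to ``t_end`` and returns a
    Trajectory.  For each frequency the peak-to-peak amplitude of the
    readout component over the final ``measure_time`` window is recorded;
    rectification during the scan signals that the amplitude is too
    large.  Returns ``(freqs, amplitudes, peak_freq)``.
    """
    freqs = np.asarray(freqs, dtype=float)
    amps = np.empty(len(freqs))
    for k, f in enumerate(freqs):
        t_end = settle_time + measure_time
        traj = run_fn(f, t_end)
        if traj.n_events:
            raise RuntimeError(
                f"rectification during resonance scan at f={f:.4g}: "
                "stimulus amplitude too large"
            )
        mask = traj.ts >= settle_time
        v = traj.xs[mask, readout]
        amps[k] = v.max() - v.min()
    return freqs, amps, float(freqs[np.argmax(amps)])
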