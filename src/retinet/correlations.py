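"""Voltage and spike correlations of the retinal network under noise.

Under white-noise forcing the non-rectified network is a multivariate
Ornstein-Uhlenbeck process: its stationary covariance solves the
continuous-time Lyapunov equation of the rest transport operator and
admits an equivalent eigenmode expansion.  Ganglion-cell spike statistics
follow by passing the Gaussian voltage law through the LNP nonlinearity:
rates are Gaussian CDFs of the mean over the pooled (intrinsic + network)
standard deviation, and pairwise spike probabilities are two-dimensional
Gaussian integrals over the principal axes of the 2x2 voltage covariance.

Lag convention: ``C(t, t') = Cov(X(t), X(t'))`` with ``t' >= t``, i.e.
``C(lag) = Sigma exp(L^T lag)``; validated against simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.integrate import quad, quad_vec
from scipy.linalg import expm, solve_continuous_lyapunov
from scipy.special import ndtr

from .core import ConnectivityMatrices, RetinaParams
from .dynamics import DomainIndex, TransportOperator, build_transport_operator, rest_state
from .spectral import SpectralDecomposition, decompose
from .stimuli import SpatioTemporalKernel

__all__ = [
    "CovarianceMatrix",
    "PairSpikeStats",
    "DeltaCorrelated",
    "drive_correlation",
    "forcing_correlation",
    "forcing_correlation_matrix",
    "stationary_covariance",
    "spectral_stationary_covariance",
    "nonstationary_covariance",
    "firing_rate",
    "pair_spike_probability",
    "nonlinearity_decorrelation_check",
    "spike_correlation_pipeline",
]


# --------------------------------------------------------------------------
# kernel-level (drive / forcing) correlations
# --------------------------------------------------------------------------

def _spatial_overlap(ki: SpatioTemporalKernel, kj: SpatioTemporalKernel,
                     dx: float = 0.01) -> float:
    """Quadrature of the product of the two spatial profiles."""
    (xi, yi), (xj, yj) = ki.center, kj.center
    r = max(ki.spatial.support_radius, kj.spatial.support_radius)
    x0, x1 = min(xi, xj) - r, max(xi, xj) + r
    y0, y1 = min(yi, yj) - r, max(yi, yj) + r
    nx = max(int(np.ceil((x1 - x0) / dx)), 16)
    ny = max(int(np.ceil((y1 - y0) / dx)), 16)
    xs = np.linspace(x0, x1, nx + 1)
    ys = np.linspace(y0, y1, ny + 1)
    pi = ki.spatial(xs[:, None] - xi, ys[None, :] - yi)
    pj = kj.spatial(xs[:, None] - xj, ys[None, :] - yj)
    return float(np.trapezoid(np.trapezoid(pi * pj, ys, axis=1), xs))


def _temporal_overlap(fi, fj, lag: float, t_max: float) -> float:
    """``int_0^inf fi(u) fj(u + lag) du`` for causal profiles."""
    val, _ = quad(lambda u: fi(u) * fj(u + lag), 0.0, t_max, limit=400)
    return val


def drive_correlation(
    ki: SpatioTemporalKernel,
    kj: SpatioTemporalKernel,
    sigma_s: float,
    lag: float = 0.0,
    dx: float = 0.01,
) -> float:
    """Covariance of two bipolar drives under spatio-temporal white noise.

    Receptive-field overlap makes drives of nearby bipolar cells
    correlated: the covariance is the noise intensity squared times the
    product of the spatial overlap integral and the temporal overlap at
    the requested lag (``lag = t' - t``); it is symmetric under
    ``(i, j, lag) <-> (j, i, -lag)`` and decays with centre distance.
    """
    if lag < 0:
        return drive_correlation(kj, ki, sigma_s, -lag, dx)
    t_max = max(ki.temporal.support, kj.temporal.support)
    return (
        sigma_s**2
        * _spatial_overlap(ki, kj, dx)
        * _temporal_overlap(ki.temporal, kj.temporal, lag, t_max)
    )


def forcing_correlation(
    ki: SpatioTemporalKernel,
    kj: SpatioTemporalKernel,
    tau_b: float,
    sigma_s: float,
    lag: float = 0.0,
    dx: float = 0.01,
) -> float:
    """Covariance of the OPL forcing terms of two bipolar cells.

    The forcing is ``drive / tau_b + d(drive)/dt``, so its covariance is
    the four-term combination of kernel x kernel, kernel x derivative and
    derivative x derivative overlaps weighted ``1/tau_b**2``, ``1/tau_b``,
    ``1/tau_b`` and 1.
    """
    if lag < 0:
        return forcing_correlation(kj, ki, tau_b, sigma_s, -lag, dx)
    t_max = max(ki.temporal.support, kj.temporal.support)
    sp = _spatial_overlap(ki, kj, dx)
    kt_i, kt_j = ki.temporal, kj.temporal
    di, dj = ki.temporal.derivative, kj.temporal.derivative
    terms = (
        _temporal_overlap(kt_i, kt_j, lag, t_max) / tau_b**2
        + _temporal_overlap(kt_i, dj, lag, t_max) / tau_b
        + _temporal_overlap(di, kt_j, lag, t_max) / tau_b
        + _temporal_overlap(di, dj, lag, t_max)
    )
    return sigma_s**2 * sp * terms


def forcing_correlation_matrix(
    kernels: list[SpatioTemporalKernel],
    tau_b: float,
    sigma_s: float,
    n_total: int,
    lag: float = 0.0,
    dx: float = 0.01,
) -> np.ndarray:
    """N x N forcing covariance: the bipolar block from
    :func:`forcing_correlation`, zeros elsewhere (amacrine and ganglion
    cells receive no direct stimulus drive)."""
    nb = len(kernels)
    out = np.zeros((n_total, n_total))
    for i in range(nb):
        for j in range(nb):
            out[i, j] = forcing_correlation(
                kernels[i], kernels[j], tau_b, sigma_s, lag, dx
            )
    return out


# --------------------------------------------------------------------------
# network (OU) covariances
# --------------------------------------------------------------------------

@dataclass
class CovarianceMatrix:
    """Stationary voltage covariance of the linear network under noise."""

    sigma: np.ndarray  # equal-time covariance, N x N
    L: np.ndarray
    sigma_s: float

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.L = np.asarray(self.L, dtype=float)

    def lag(self, tau: float) -> np.ndarray:
        """Lagged covariance Cov(X(t), X(t + tau))."""
        if tau >= 0:
            return self.sigma @ expm(self.L.T * tau)
        return expm(self.L * (-tau)) @ self.sigma


def spectral_stationary_covariance(
    decomp: SpectralDecomposition, sigma_s: float, Q: np.ndarray | None = None
) -> np.ndarray:
    """Eigenmode expansion of the stationary covariance.

    ``Sigma = -sigma_s**2 sum_ab (w_a Q w_b^T) / (lam_a + lam_b)
              v_a v_b^T`` with right eigenvectors ``v`` and left
    eigenvectors ``w``; complex conjugate modes combine to a real matrix.
    """
    if not decomp.stable:
        raise ValueError("no stationary covariance for an unstable operator")
    n = decomp.L.shape[0]
    Q = np.eye(n) if Q is None else np.asarray(Q, dtype=float)
    lam = decomp.eigenvalues
    M = decomp.Pinv @ Q @ decomp.Pinv.T
    denom = lam[:, None] + lam[None, :]
    sigma = -(sigma_s**2) * decomp.P @ (M / denom) @ decomp.P.T
    resid = np.abs(sigma.imag).max()
    scale = max(np.abs(sigma.real).max(), 1e-300)
    if resid > 1e-10 * scale:
        raise RuntimeError(f"imaginary residue {resid:.3g} in spectral covariance")
    return sigma.real


def stationary_covariance(
    op,
    sigma_s: float,
    Q: np.ndarray | None = None,
    check_spectral: bool = True,
    tol: float = 1e-8,
) -> CovarianceMatrix:
    """Stationary covariance of ``dX = L X dt + sigma_s B dW``.

    Solves the continuous-time Lyapunov stationarity condition
    ``L Sigma + Sigma L^T = -sigma_s**2 Q`` (``Q = B B^T``, identity by
    default) and, unless disabled, cross-validates against the eigenmode
    expansion to ``tol``.
    """
    L = op.L if isinstance(op, TransportOperator) else np.asarray(op, dtype=float)
    if np.any(np.linalg.eigvals(L).real >= 0):
        raise ValueError("no stationary covariance for an unstable operator")
    n = L.shape[0]
    Qm = np.eye(n) if Q is None else np.asarray(Q, dtype=float)
    sigma = solve_continuous_lyapunov(L, -(sigma_s**2) * Qm)
    sigma = 0.5 * (sigma + sigma.T)
    if check_spectral:
        decomp = decompose(L)
        if decomp.diagonalizable:
            spec = spectral_stationary_covariance(decomp, sigma_s, Qm)
            err = np.abs(spec - sigma).max() / max(np.abs(sigma).max(), 1e-300)
            if err > tol:
                raise RuntimeError(
                    f"spectral and Lyapunov covariances disagree (rel {err:.3g})"
                )
    return CovarianceMatrix(sigma=sigma, L=L, sigma_s=sigma_s)


@dataclass(frozen=True)
class DeltaCorrelated:
    """Marker for white (delta-correlated) forcing with spatial profile Q."""

    sigma_s: float
    Q: np.ndarray | None = None


def nonstationary_covariance(
    L: np.ndarray,
    cf,
    t: float,
    t_prime: float,
    t0: float = -np.inf,
    tol: float = 1e-10,
) -> np.ndarray:
    """Covariance of the network response to correlated forcing.

    ``C(t, t') = int int exp(L (t - s)) CF(s, s') exp(L^T (t' - s'))``
    over ``s <= t``, ``s' <= t'`` starting from ``t0``.  ``cf`` is either
    a callable ``(s, s') -> (N, N)`` (double quadrature) or a
    :class:`DeltaCorrelated` marker, for which the double integral
    collapses to a single one and, for ``t0 = -inf``, to the stationary
    covariance propagated to the requested lag.
    """
    L = np.asarray(L, dtype=float)
    n = L.shape[0]
    if isinstance(cf, DeltaCorrelated):
        Q = np.eye(n) if cf.Q is None else np.asarray(cf.Q, dtype=float)
        lo = min(t, t_prime)
        if np.isinf(t0):
            cov = stationary_covariance(L, cf.sigma_s, Q, check_spectral=False)
            return cov.lag(t_prime - t)
        def integrand(s):
            return cf.sigma_s**2 * expm(L * (t - s)) @ Q @ expm(L.T * (t_prime - s))
        val, _ = quad_vec(integrand, t0, lo, epsabs=tol, epsrel=tol)
        return val
    if np.isinf(t0):
        raise ValueError("general forcing correlations require a finite t0")
    def outer(s):
        def inner(sp):
            return np.asarray(cf(s, sp), dtype=float) @ expm(L.T * (t_prime - sp))
        val, _ = quad_vec(inner, t0, t_prime, epsabs=tol, epsrel=tol)
        return expm(L * (t - s)) @ val
    val, _ = quad_vec(outer, t0, t, epsabs=tol, epsrel=tol)
    return val


# --------------------------------------------------------------------------
# LNP spike statistics
# --------------------------------------------------------------------------

def firing_rate(m, var_net, theta_g: float, sigma_g: float):
    """Spiking probability of an LNP cell with Gaussian voltage.

    Averaging the LNP sigmoid over a Normal(m, var_net) voltage gives
    ``Phi((m - theta_g) / sqrt(sigma_g**2 + var_net))``: intrinsic and
    network noise variances add.
    """
    if sigma_g <= 0:
        raise ValueError("sigma_g must be strictly positive")
    var_net = np.asarray(var_net, dtype=float)
    if np.any(var_net < 0):
        raise ValueError("network variance must be non-negative")
    m = np.asarray(m, dtype=float)
    out = ndtr((m - theta_g) / np.sqrt(sigma_g**2 + var_net))
    return float(out) if out.ndim == 0 else out


@dataclass
class PairSpikeStats:
    """Joint spike statistics of two LNP cells with Gaussian voltages."""

    nu1: float
    nu2: float
    nu12: float
    var1: float
    var2: float
    c12: float
    phi: float   # rotation diagonalising the 2x2 voltage covariance
    mu1: float   # principal standard deviations
    mu2: float

    @property
    def spike_covariance(self) -> float:
        return self.nu12 - self.nu1 * self.nu2


def _gh_nodes(order: int):
    x, w = hermegauss(order)
    return x, w / np.sqrt(2 * np.pi)


def pair_spike_probability(
    m1: float,
    m2: float,
    cov2x2: np.ndarray,
    theta_g: float,
    sigma_g: float,
    order: int = 40,
    refine_tol: float = 1e-10,
    max_order: int = 640,
) -> PairSpikeStats:
    """Joint spiking probability of two LNP cells.

    The 2x2 voltage covariance is diagonalised by a rotation ``phi``; the
    joint probability is the double Gaussian integral of the product of
    the two LNP sigmoids along the principal axes (standard deviations
    ``mu1``, ``mu2``), evaluated by tensorised Gauss-Hermite quadrature.
    The result must be stable under doubling the quadrature order to
    ``refine_tol``, otherwise the computation aborts.  With a diagonal
    covariance the integral factorises into the product of the rates.
    """
    C = np.asarray(cov2x2, dtype=float)
    if C.shape != (2, 2) or abs(C[0, 1] - C[1, 0]) > 1e-10 * max(1.0, abs(C).max()):
        raise ValueError("cov2x2 must be symmetric 2x2")
    evals, evecs = np.linalg.eigh(C)
    if evals[0] < -1e-12 * max(1.0, evals[-1]):
        raise ValueError("cov2x2 must be positive semi-definite")
    evals = np.clip(evals, 0.0, None)
    mu = np.sqrt(evals)
    phi = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    A = evecs * mu[None, :]  # V = m + A Y, Y ~ N(0, I)

    def joint(ord_):
        x, w = _gh_nodes(ord_)
        y1 = x[:, None]
        y2 = x[None, :]
        v1 = m1 + A[0, 0] * y1 + A[0, 1] * y2
        v2 = m2 + A[1, 0] * y1 + A[1, 1] * y2
        f = ndtr((v1 - theta_g) / sigma_g) * ndtr((v2 - theta_g) / sigma_g)
        return float(w @ f @ w)

    # escalate the order until the doubled-order refinement is inert; the
    # quadrature converges slowly when the network standard deviation far
    # exceeds sigma_g (the sigmoid then acts as a step on the Gaussian
    # scale), in which case the computation refuses rather than returning
    # an unconverged value.
    nu12 = joint(order)
    converged = False
    while order <= max_order:
        refined = joint(2 * order)
        if abs(refined - nu12) < refine_tol:
            nu12 = refined
            converged = True
            break
        nu12 = refined
        order *= 2
    if not converged:
        raise RuntimeError("Gauss-Hermite quadrature not converged; raise order")
    nu1 = firing_rate(m1, C[0, 0], theta_g, sigma_g)
    nu2 = firing_rate(m2, C[1, 1], theta_g, sigma_g)
    return PairSpikeStats(
        nu1=nu1, nu2=nu2, nu12=nu12,
        var1=float(C[0, 0]), var2=float(C[1, 1]), c12=float(C[0, 1]),
        phi=phi, mu1=float(mu[0]), mu2=float(mu[1]),
    )


def nonlinearity_decorrelation_check(
    rhos,
    f=None,
    order: int = 80,
) -> pd.DataFrame:
    """Output correlation of a nonlinearity applied to correlated Gaussians.

    For standard bivariate normal inputs with correlation ``rho``, the
    correlation of ``(f(V1), f(V2))`` is computed by two-dimensional
    Gauss-Hermite quadrature.  Passing two jointly Gaussian signals
    through any nonlinearity can only shrink their correlation in
    magnitude, so ``|corr_out| <= |rho|`` row by row.
    """
    if f is None:
        f = ndtr
    rhos = np.atleast_1d(np.asarray(rhos, dtype=float))
    if np.any(np.abs(rhos) >= 1):
        raise ValueError("|rho| must be < 1")
    x, w = _gh_nodes(order)
    fx = f(x)
    mean_f = float(w @ fx)
    var_f = float(w @ (fx - mean_f) ** 2)
    out = []
    for rho in rhos:
        v2 = rho * x[:, None] + np.sqrt(1 - rho**2) * x[None, :]
        e12 = float(w @ (fx[:, None] * f(v2)) @ w)
        corr = (e12 - mean_f**2) / var_f if var_f > 0 else 0.0
        out.append((rho, corr))
    df = pd.DataFrame(out, columns=["rho_in", "rho_out"])
    df["attenuated"] = np.abs(df["rho_out"]) <= np.abs(df["rho_in"]) + 1e-12
    return df


def spike_correlation_pipeline(
    params: RetinaParams,
    conn: ConnectivityMatrices,
    sigma_s: float,
    mean_voltages: np.ndarray | None = None,
    lag: float = 0.0,
    Q: np.ndarray | None = None,
    gh_order: int = 40,
):
    """Pairwise spike covariance of all ganglion cells under white noise.

    Composes the stationary network covariance (ganglion block), the mean
    ganglion voltages (rest state unless supplied), the LNP rate formula
    and the pairwise Gaussian integral.  Returns a dict with ``rates``,
    ``joint`` and ``spike_cov`` (NG x NG arrays) plus the underlying
    voltage covariance.  Only valid in the stable, non-rectified regime;
    a rest state outside the rest domain triggers a warning upstream.
    """
    nb, na, ng = conn.nb, conn.na, conn.ng
    dom0 = DomainIndex(eta=(0,) * (nb + na))
    op = build_transport_operator(dom0, params, conn)
    cov = stationary_covariance(op, sigma_s, Q=Q)
    if mean_voltages is None:
        mean_voltages = rest_state(params, conn)
    m_g = np.asarray(mean_voltages, dtype=float)[nb + na :]
    sl = slice(nb + na, nb + na + ng)
    sigma_gg = cov.lag(lag)[sl, sl] if lag else cov.sigma[sl, sl]
    var_g = np.diag(cov.sigma)[sl]
    rates = firing_rate(m_g, var_g, params.theta_g, params.sigma_g)
    joint = np.zeros((ng, ng))
    spike_cov = np.zeros((ng, ng))
    for i in range(ng):
        for j in range(ng):
            if i == j and lag == 0.0:
                joint[i, j] = rates[i]
                spike_cov[i, j] = rates[i] * (1 - rates[i])
                continue
            c = np.array(
                [[var_g[i], sigma_gg[i, j]], [sigma_gg[j, i] if lag == 0 else sigma_gg[i, j], var_g[j]]]
            )
            c[1, 0] = c[0, 1]
            stats = pair_spike_probability(
                m_g[i], m_g[j], c, params.theta_g, params.sigma_g, order=gh_order
            )
            joint[i, j] = stats.nu12
            spike_cov[i, j] = stats.spike_covariance
    return {
        "rates": rates,
        "joint": joint,
        "spike_cov": spike_cov,
        "voltage_cov": cov,
    }
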