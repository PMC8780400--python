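"""Spatio-temporal stimuli, B-cell receptive-field kernels and OPL forcing.

The stimulus stage is summarised by a causal space-time kernel per bipolar
cell: the cell's drive voltage is the space-time convolution of the kernel
with the stimulus, and the forcing term injected into the network dynamics
is ``drive / tau_b + d(drive)/dt`` so that, without lateral input, the
bipolar voltage tracks its drive exactly.

All shipped stimuli carry analytic time derivatives; the drive of the
derivative equals the derivative of the drive, which the forcing term
exploits.  Generated stimuli keep contrast within [0, 1] scaled by their
amplitude parameter.  The stimulus is assumed to vanish outside the
declared field of view (no periodic wrap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DoGSpatial",
    "BiphasicTemporal",
    "SpatioTemporalKernel",
    "make_dog_kernel",
    "Stimulus",
    "FullFieldFlash",
    "PeriodicFlashes",
    "ChirpSweep",
    "MovingBar",
    "compute_drive",
    "opl_forcing",
    "DriveForcing",
    "WhiteNoiseForcing",
    "exp_filter_pl",
]


# --------------------------------------------------------------------------
# kernels
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DoGSpatial:
    """Difference-of-Gaussians spatial profile (ON centre / OFF surround).

    Each Gaussian is normalised to unit mass, so the total spatial
    integral is ``w_center - w_surround``.
    """

    sigma_center: float
    sigma_surround: float
    w_center: float = 1.0
    w_surround: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_center <= 0 or self.sigma_surround <= 0:
            raise ValueError("spatial widths must be positive")
        if self.w_surround != 0.0 and self.sigma_surround <= self.sigma_center:
            raise ValueError("surround must be wider than centre")

    def __call__(self, dx, dy):
        dx = np.asarray(dx, dtype=float)
        dy = np.asarray(dy, dtype=float)
        r2 = dx**2 + dy**2
        c = self.w_center / (2 * np.pi * self.sigma_center**2) * np.exp(
            -r2 / (2 * self.sigma_center**2)
        )
        s = self.w_surround / (2 * np.pi * self.sigma_surround**2) * np.exp(
            -r2 / (2 * self.sigma_surround**2)
        )
        return c - s

    @property
    def integral(self) -> float:
        return self.w_center - self.w_surround

    @property
    def support_radius(self) -> float:
        return 5.0 * max(self.sigma_center, self.sigma_surround)


@dataclass(frozen=True)
class BiphasicTemporal:
    """Causal biphasic temporal profile vanishing at t = 0.

    ``K(t) = w1 * (t / tau1**2) * exp(-t / tau1)
           - w2 * (t / tau2**2) * exp(-t / tau2)`` for t >= 0.

    Each lobe integrates to its weight, so the temporal integral is
    ``w1 - w2``; ``K(0) = 0`` as required for the forcing construction.
    """

    tau1: float
    tau2: float
    w1: float = 1.0
    w2: float = 0.0

    def __post_init__(self) -> None:
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("temporal time constants must be positive")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        pos = t > 0
        out = np.zeros_like(t)
        tp = t[pos] if t.ndim else (t if pos else 0.0)
        val = self.w1 * tp / self.tau1**2 * np.exp(-tp / self.tau1) - (
            self.w2 * tp / self.tau2**2 * np.exp(-tp / self.tau2)
        )
        if t.ndim:
            out[pos] = val
            return out
        return float(val) if pos else 0.0

    def derivative(self, t):
        t = np.asarray(t, dtype=float)
        out = self.w1 / self.tau1**2 * (1 - t / self.tau1) * np.exp(-t / self.tau1) - (
            self.w2 / self.tau2**2 * (1 - t / self.tau2) * np.exp(-t / self.tau2)
        )
        out = np.where(t >= 0, out, 0.0)
        return float(out) if out.ndim == 0 else out

    @property
    def integral(self) -> float:
        return self.w1 - self.w2

    @property
    def support(self) -> float:
        return 12.0 * max(self.tau1, self.tau2)


@dataclass(frozen=True)
class SpatioTemporalKernel:
    """Separable, causal receptive-field kernel centred at ``center`` (mm)."""

    center: tuple[float, float]
    spatial: DoGSpatial
    temporal: BiphasicTemporal

    def __call__(self, x, y, t):
        xc, yc = self.center
        return self.spatial(np.asarray(x) - xc, np.asarray(y) - yc) * self.temporal(t)

    @property
    def spatial_integral(self) -> float:
        return self.spatial.integral

    @property
    def temporal_integral(self) -> float:
        return self.temporal.integral


def make_dog_kernel(
    sigma_center: float,
    sigma_surround: float,
    w_center: float = 1.0,
    w_surround: float = 0.0,
    tau1: float = 5.0,
    tau2: float = 10.0,
    wt1: float = 1.0,
    wt2: float = 0.0,
    center: tuple[float, float] = (0.0, 0.0),
) -> SpatioTemporalKernel:
    """Build a separable DoG x biphasic receptive-field kernel."""
    return SpatioTemporalKernel(
        center=center,
        spatial=DoGSpatial(sigma_center, sigma_surround, w_center, w_surround),
        temporal=BiphasicTemporal(tau1, tau2, wt1, wt2),
    )


# --------------------------------------------------------------------------
# stimuli
# --------------------------------------------------------------------------

class Stimulus:
    """Deterministic spatio-temporal contrast field.

    Subclasses implement ``value(x, y, t)`` and the analytic time
    derivative ``dt(x, y, t)``; full-field stimuli set ``is_fullfield``
    and expose scalar ``field(t)`` / ``field_dt(t)`` fast paths.
    """

    is_fullfield = False

    def value(self, x, y, t):
        raise NotImplementedError

    def dt(self, x, y, t):
        raise NotImplementedError


def _smooth_pulse(t, t_on, t_off, ramp):
    """C1 rectangle with raised-cosine edges of half-width ``ramp``."""
    t = np.asarray(t, dtype=float)
    up = np.clip((t - t_on) / ramp, 0.0, 1.0)
    down = np.clip((t_off - t) / ramp, 0.0, 1.0)
    return 0.5 * (1 - np.cos(np.pi * up)) * 0.5 * (1 - np.cos(np.pi * down))


def _smooth_pulse_dt(t, t_on, t_off, ramp):
    t = np.asarray(t, dtype=float)
    up = np.clip((t - t_on) / ramp, 0.0, 1.0)
    down = np.clip((t_off - t) / ramp, 0.0, 1.0)
    du = np.where((t > t_on) & (t < t_on + ramp), np.pi / ramp * np.sin(np.pi * up), 0.0)
    dd = np.where(
        (t > t_off - ramp) & (t < t_off), -np.pi / ramp * np.sin(np.pi * down), 0.0
    )
    f_up = 0.5 * (1 - np.cos(np.pi * up))
    f_down = 0.5 * (1 - np.cos(np.pi * down))
    return 0.5 * du * f_down + 0.5 * dd * f_up


@dataclass(frozen=True)
class FullFieldFlash(Stimulus):
    """Full-field flash of given contrast with smooth on/off ramps (ms)."""

    contrast: float = 1.0
    t_on: float = 0.0
    t_off: float = 50.0
    ramp: float = 2.0

    is_fullfield = True

    def field(self, t):
        return self.contrast * _smooth_pulse(t, self.t_on, self.t_off, self.ramp)

    def field_dt(self, t):
        return self.contrast * _smooth_pulse_dt(t, self.t_on, self.t_off, self.ramp)

    def value(self, x, y, t):
        return np.broadcast_to(self.field(t), np.broadcast_shapes(
            np.shape(x), np.shape(y), np.shape(t))).copy()

    def dt(self, x, y, t):
        return np.broadcast_to(self.field_dt(t), np.broadcast_shapes(
            np.shape(x), np.shape(y), np.shape(t))).copy()


@dataclass(frozen=True)
class PeriodicFlashes(Stimulus):
    """Periodic train of brief full-field flashes (raised-cosine pulses).

    ``period`` in ms, ``width`` the full pulse width in ms.  The pulse
    shape ``0.5 * (1 - cos(2 pi s))`` concentrates power at the train
    fundamental, which keeps resonance scans dominated by it.
    """

    period: float
    width: float
    contrast: float = 1.0
    t_start: float = 0.0

    is_fullfield = True

    def __post_init__(self) -> None:
        if self.width >= self.period:
            raise ValueError("pulse width must be smaller than the period")

    def field(self, t):
        t = np.asarray(t, dtype=float) - self.t_start
        phase = np.mod(t, self.period)
        s = phase / self.width
        pulse = np.where((s > 0) & (s < 1), 0.5 * (1 - np.cos(2 * np.pi * s)), 0.0)
        return self.contrast * np.where(t >= 0, pulse, 0.0)

    def field_dt(self, t):
        t = np.asarray(t, dtype=float) - self.t_start
        phase = np.mod(t, self.period)
        s = phase / self.width
        d = np.where(
            (s > 0) & (s < 1),
            np.pi / self.width * np.sin(2 * np.pi * s),
            0.0,
        )
        return self.contrast * np.where(t >= 0, d, 0.0)

    def value(self, x, y, t):
        return np.broadcast_to(self.field(t), np.broadcast_shapes(
            np.shape(x), np.shape(y), np.shape(t))).copy()

    def dt(self, x, y, t):
        return np.broadcast_to(self.field_dt(t), np.broadcast_shapes(
            np.shape(x), np.shape(y), np.shape(t))).copy()


@dataclass(frozen=True)
class ChirpSweep(Stimulus):
    """Full-field sinusoidal sweep with linearly increasing frequency.

    Instantaneous frequency ramps from ``f0`` to ``f1`` (cycles/ms) over
    ``duration`` ms; contrast oscillates in [0, contrast].
    """

    f0: float
    f1: float
    duration: float
    contrast: float = 1.0

    is_fullfield = True

    def _phase(self, t):
        k = (self.f1 - self.f0) / self.duration
        return 2 * np.pi * (self.f0 * t + 0.5 * k * t**2)

    def field(self, t):
        t = np.asarray(t, dtype=float)
        inside = (t >= 0) & (t <= self.duration)
        return np.where(
            inside, 0.5 * self.contrast * (1 - np.cos(self._phase(t))), 0.0
        )

    def field_dt(self, t):
        t = np.asarray(t, dtype=float)
        k = (self.f1 - self.f0) / self.duration
        omega = 2 * np.pi * (self.f0 + k * t)
        inside = (t >= 0) & (t <= self.duration)
        return np.where(
            inside, 0.5 * self.contrast * omega * np.sin(self._phase(t)), 0.0
        )

    def value(self, x, y, t):
        return np.broadcast_to(self.field(t), np.broadcast_shapes(
            np.shape(x), np.shape(y), np.shape(t))).copy()

    def dt(self, x, y, t):
        return np.broadcast_to(self.field_dt(t), np.broadcast_shapes(
            np.shape(x), np.shape(y), np.shape(t))).copy()


@dataclass(frozen=True)
class MovingBar(Stimulus):
    """Gaussian-profile bar, uniform along y, moving along x at ``speed``.

    ``S(x, y, t) = contrast * exp(-(x - x0 - speed * t)**2 / (2 width**2))``.
    Speed in mm/ms, width in mm.
    """

    contrast: float = 1.0
    speed: float = 0.01
    width: float = 0.1
    x0: float = 0.0

    def _arg(self, x, t):
        return np.asarray(x, dtype=float) - self.x0 - self.speed * np.asarray(t, dtype=float)

    def value(self, x, y, t):
        u = self._arg(x, t)
        out = self.contrast * np.exp(-(u**2) / (2 * self.width**2))
        return np.broadcast_to(out, np.broadcast_shapes(
            np.shape(x), np.shape(y), np.shape(t))).copy()

    def dt(self, x, y, t):
        u = self._arg(x, t)
        out = (
            self.contrast
            * np.exp(-(u**2) / (2 * self.width**2))
            * (u * self.speed / self.width**2)
        )
        return np.broadcast_to(out, np.broadcast_shapes(
            np.shape(x), np.shape(y), np.shape(t))).copy()


# --------------------------------------------------------------------------
# drive & forcing
# --------------------------------------------------------------------------

def _time_grid(kernel: SpatioTemporalKernel, dt: float):
    n = max(int(np.ceil(kernel.temporal.support / dt)), 8)
    u = np.linspace(0.0, kernel.temporal.support, n + 1)
    w = np.full(n + 1, u[1] - u[0])
    w[0] = w[-1] = 0.5 * (u[1] - u[0])
    return u, w


def compute_drive(
    kernel: SpatioTemporalKernel,
    stimulus: Stimulus,
    t,
    *,
    dt: float = 0.05,
    dx: float = 0.02,
    derivative: bool = False,
):
    """Space-time convolution of the kernel with the stimulus at time(s) t.

    The convolution is evaluated by direct summation on a grid covering
    the kernel support (``dt`` ms in time, ``dx`` mm in space); full-field
    stimuli reduce to a one-dimensional temporal quadrature scaled by the
    spatial integral.  With ``derivative=True`` the stimulus' analytic
    time derivative is convolved instead, yielding d(drive)/dt.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    u, wu = _time_grid(kernel, dt)
    kt = kernel.temporal(u)
    source = stimulus.dt if derivative else stimulus.value
    if stimulus.is_fullfield:
        f = stimulus.field_dt if derivative else stimulus.field
        s = f(t_arr[:, None] - u[None, :])
        vals = kernel.spatial_integral * np.sum(s * (kt * wu)[None, :], axis=1)
    else:
        xc, yc = kernel.center
        r = kernel.spatial.support_radius
        nx = max(int(np.ceil(2 * r / dx)), 8)
        xs = np.linspace(xc - r, xc + r, nx + 1)
        ys = np.linspace(yc - r, yc + r, nx + 1)
        ks = kernel.spatial(xs[:, None] - xc, ys[None, :] - yc)
        wx = np.full(nx + 1, xs[1] - xs[0])
        wx[0] = wx[-1] = 0.5 * (xs[1] - xs[0])
        w2d = ks * (wx[:, None] * wx[None, :])
        vals = np.empty_like(t_arr)
        for i, ti in enumerate(t_arr):
            s = source(xs[:, None, None], ys[None, :, None], ti - u[None, None, :])
            vals[i] = np.sum(s * w2d[:, :, None] * (kt * wu)[None, None, :])
    return float(vals[0]) if np.ndim(t) == 0 else vals


def opl_forcing(
    kernel: SpatioTemporalKernel,
    stimulus: Stimulus,
    tau_b: float,
    t,
    **kwargs,
):
    """OPL forcing term ``drive / tau_b + d(drive)/dt``.

    Integrating ``dV/dt = -V / tau_b + F`` from rest reproduces the drive
    voltage exactly, so an uncoupled bipolar cell tracks its drive.
    """
    drive = compute_drive(kernel, stimulus, t, **kwargs)
    ddrive = compute_drive(kernel, stimulus, t, derivative=True, **kwargs)
    return drive / tau_b + ddrive


def exp_filter_pl(lmbda: complex, ts: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Exact causal exponential filtering of a piecewise-linear signal.

    Returns ``y(t_k) = int_{t_0}^{t_k} exp(lmbda (t_k - s)) v(s) ds`` where
    ``v`` is linearly interpolated between samples (zero before ``t_0``).
    The per-step update is exact for the interpolant, so the only error
    is the interpolation error of ``v`` itself.
    """
    ts = np.asarray(ts, dtype=float)
    v = np.asarray(v)
    dt = np.diff(ts)
    if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
        raise ValueError("exp_filter_pl requires a uniform time grid")
    h = dt[0]
    lam = complex(lmbda)
    y = np.zeros(len(ts), dtype=complex)
    if abs(lam) * h < 1e-8:
        # trapezoid limit of the exact kernel weights
        e = 1.0
        w0 = h / 2
        w1 = h / 2
    else:
        e = np.exp(lam * h)
        # int_0^h e^{lam (h-s)} * (1 - s/h) ds  and  * (s/h) ds
        w0 = (e - 1.0) / lam - (e - 1.0 - lam * h) / (lam**2 * h)
        w1 = (e - 1.0 - lam * h) / (lam**2 * h)
    for k in range(1, len(ts)):
        y[k] = e * y[k - 1] + w0 * v[k - 1] + w1 * v[k]
    return y


class DriveForcing:
    """Network forcing built from per-B-cell drive voltages.

    Drives are stored as samples on a uniform master grid and linearly
    interpolated; the forcing vector is ``drive / tau_b + d(drive)/dt``
    on the B rows and zero on A and G rows.  Using the interpolant (and
    its exact piecewise-constant derivative) as *the* forcing definition
    makes event-driven integration, reference integration and spectral
    closed forms mutually consistent to solver precision.
    """

    def __init__(self, ts: np.ndarray, drives: np.ndarray, tau_b, n_total: int):
        self.ts = np.asarray(ts, dtype=float)
        self.drives = np.atleast_2d(np.asarray(drives, dtype=float))
        self.nb = self.drives.shape[0]
        self.n_total = n_total
        self.tau_b = np.broadcast_to(np.asarray(tau_b, dtype=float), (self.nb,))
        if self.drives.shape[1] != len(self.ts):
            raise ValueError("drives must be sampled on ts")
        self._h = self.ts[1] - self.ts[0]
        self._slopes = np.diff(self.drives, axis=1) / self._h

    @classmethod
    def from_stimulus(
        cls,
        kernels,
        stimulus: Stimulus,
        tau_b,
        ts: np.ndarray,
        n_total: int,
        **drive_kwargs,
    ) -> "DriveForcing":
        drives = np.array(
            [compute_drive(k, stimulus, ts, **drive_kwargs) for k in kernels]
        )
        return cls(ts, drives, tau_b, n_total)

    def drive(self, t):
        """Interpolated drive vector (length NB) at time t."""
        t = float(t)
        if t <= self.ts[0]:
            return self.drives[:, 0].copy()
        if t >= self.ts[-1]:
            return self.drives[:, -1].copy()
        k = int((t - self.ts[0]) // self._h)
        k = min(k, len(self.ts) - 2)
        frac = (t - self.ts[k]) / self._h
        return self.drives[:, k] * (1 - frac) + self.drives[:, k + 1] * frac

    def drive_dt(self, t):
        t = float(t)
        if t < self.ts[0] or t > self.ts[-1]:
            return np.zeros(self.nb)
        k = int((t - self.ts[0]) // self._h)
        k = min(k, self._slopes.shape[1] - 1)
        return self._slopes[:, k].copy()

    def __call__(self, t) -> np.ndarray:
        out = np.zeros(self.n_total)
        out[: self.nb] = self.drive(t) / self.tau_b + self.drive_dt(t)
        return out

    def interval_endpoint_values(self, s0: float, s1: float):
        """One-sided forcing vectors at the ends of a kink-free interval.

        The forcing's derivative part is piecewise constant, hence
        discontinuous at grid nodes; exact convolution needs the values
        taken *within* the interval ``(s0, s1)``, identified by its
        midpoint.
        """
        mid = 0.5 * (s0 + s1)
        out0 = np.zeros(self.n_total)
        out1 = np.zeros(self.n_total)
        if mid <= self.ts[0] or mid >= self.ts[-1]:
            base = self.drive(mid) / self.tau_b
            out0[: self.nb] = base
            out1[: self.nb] = base
            return out0, out1
        k = min(int((mid - self.ts[0]) // self._h), self._slopes.shape[1] - 1)
        slope = self._slopes[:, k]
        for out, s in ((out0, s0), (out1, s1)):
            vd = self.drives[:, k] + slope * (s - self.ts[k])
            out[: self.nb] = vd / self.tau_b + slope
        return out0, out1


class WhiteNoiseForcing:
    """Forcing-level white noise ``F(t) = m(t) + sigma_s * xi(t)``.

    ``xi`` is a standard vector white noise realised by the integrator's
    Euler-Maruyama scheme; by default only B rows are driven (A and G
    cells receive no direct stimulus input), the full-vector variant is
    available for covariance validation.
    """

    def __init__(self, mean, sigma_s: float, n_total: int, nb: int | None = None,
                 b_only: bool = True, seed: int | None = None):
        if sigma_s < 0:
            raise ValueError("sigma_s must be non-negative")
        self.sigma_s = float(sigma_s)
        self.n_total = n_total
        self.nb = nb if nb is not None else n_total
        self.b_only = b_only
        self.seed = seed
        if callable(mean):
            self._mean = mean
        else:
            m = np.zeros(n_total) if mean is None else np.asarray(mean, dtype=float)
            self._mean = lambda t, m=m: m

    def mean(self, t) -> np.ndarray:
        return np.asarray(self._mean(t), dtype=float)

    def noise_mask(self) -> np.ndarray:
        mask = np.ones(self.n_total)
        if self.b_only:
            mask[self.nb:] = 0.0
        return mask

    def __call__(self, t) -> np.ndarray:
        return self.mean(t)
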