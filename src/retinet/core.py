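"""Domain types and static nonlinearities of the layered retina model.

The model stacks three square lattices of cells — bipolar (B), amacrine (A)
and ganglion (G) — on a common field of view.  B cells are driven by the
stimulus through their receptive fields, A cells provide lateral inhibition,
and G cells pool both populations and spike through an LNP mechanism.
Synaptic transmission is rectified below a voltage threshold, which makes
the joint voltage dynamics piecewise linear.

Units: voltages in mV, time in ms, space in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import ndtr

__all__ = [
    "LAYERS",
    "LayerGeometry",
    "RetinaParams",
    "ConnectivityMatrices",
    "StateVector",
    "rectify_linear",
    "lnp_nonlinearity",
    "gain_function",
    "binary_gain",
    "index_map",
    "inverse_index_map",
]

LAYERS = ("B", "A", "G")


def index_map(ix: int, iy: int, lp: int) -> int:
    """Map 1-based lattice coordinates (ix, iy) to the 1-based cell index.

    The map ``i = ix + (iy - 1) * lp`` is a bijection from the lattice
    ``{1..lp}^2`` onto ``{1..lp^2}``.
    """
    ix_a = np.asarray(ix)
    iy_a = np.asarray(iy)
    if np.any(ix_a < 1) or np.any(ix_a > lp) or np.any(iy_a < 1) or np.any(iy_a > lp):
        raise ValueError(f"lattice coordinates must lie in [1, {lp}]")
    out = ix_a + (iy_a - 1) * lp
    return int(out) if out.ndim == 0 else out


def inverse_index_map(i: int, lp: int) -> tuple[int, int]:
    """Recover (ix, iy) from the 1-based cell index."""
    i_a = np.asarray(i)
    if np.any(i_a < 1) or np.any(i_a > lp * lp):
        raise ValueError(f"index must lie in [1, {lp * lp}]")
    iy = (i_a - 1) // lp + 1
    ix = i_a - (iy - 1) * lp
    if i_a.ndim == 0:
        return int(ix), int(iy)
    return ix, iy


@dataclass(frozen=True)
class LayerGeometry:
    """Square-lattice geometry of the three cell layers.

    Parameters
    ----------
    edge_mm:
        Edge length ``L`` of the (square) field of view, in mm.
    spacing_mm:
        Lattice spacing ``delta_p`` per layer, keyed by ``"B"``, ``"A"``,
        ``"G"``.  ``L`` must be an integer multiple of each spacing; the
        layer then holds ``(L / delta_p)**2`` cells.
    """

    edge_mm: float
    spacing_mm: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.edge_mm <= 0:
            raise ValueError("edge length must be positive")
        for layer in LAYERS:
            if layer not in self.spacing_mm:
                raise ValueError(f"missing spacing for layer {layer!r}")
            d = self.spacing_mm[layer]
            if d <= 0:
                raise ValueError("lattice spacing must be positive")
            ratio = self.edge_mm / d
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(
                    f"edge length {self.edge_mm} is not a multiple of "
                    f"spacing {d} (layer {layer})"
                )

    def cells_per_row(self, layer: str) -> int:
        return round(self.edge_mm / self.spacing_mm[layer])

    def n_cells(self, layer: str) -> int:
        return self.cells_per_row(layer) ** 2

    @property
    def nb(self) -> int:
        return self.n_cells("B")

    @property
    def na(self) -> int:
        return self.n_cells("A")

    @property
    def ng(self) -> int:
        return self.n_cells("G")

    def coordinates(self, layer: str) -> np.ndarray:
        """(N, 2) array of cell centre coordinates in mm, in index order."""
        lp = self.cells_per_row(layer)
        d = self.spacing_mm[layer]
        idx = np.arange(1, lp * lp + 1)
        ix, iy = inverse_index_map(idx, lp)
        return np.column_stack([ix * d, iy * d]).astype(float)


def _as_vector(value, n: int, name: str) -> np.ndarray:
    v = np.asarray(value, dtype=float)
    if v.ndim == 0:
        v = np.full(n, float(v))
    if v.shape != (n,):
        raise ValueError(f"{name} must be scalar or length-{n} vector")
    return v


@dataclass(frozen=True)
class RetinaParams:
    """Biophysical parameters of the B/A/G network.

    Time constants may be scalars (shared) or per-cell vectors; the
    vectorised form is resolved against a geometry via :meth:`resolve`.

    Attributes
    ----------
    tau_b, tau_a, tau_g:
        Membrane time constants in ms (strictly positive).
    theta_b, theta_a:
        Rectification thresholds (mV) of B- and A-cell synaptic output.
    theta_g, sigma_g:
        Threshold and slope (mV) of the LNP spiking nonlinearity.
    tau_act, h_act, theta_act:
        Gain-control parameters: activity time constant (ms), activity
        build-up rate (1/ms per mV) and the binary-gain threshold
        (dimensionless activity; 2/3 from a linear interpolation of the
        smooth gain function).
    sigma_s:
        White-noise forcing intensity (mV / sqrt(ms)); 0 disables noise.
    """

    tau_b: float | np.ndarray = 10.0
    tau_a: float | np.ndarray = 10.0
    tau_g: float | np.ndarray = 5.0
    theta_b: float = 0.0
    theta_a: float = 0.0
    theta_g: float = 1.0
    sigma_g: float = 1.0
    tau_act: float = 100.0
    h_act: float = 0.0
    theta_act: float = 2.0 / 3.0
    sigma_s: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tau_b", "tau_a", "tau_g"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"{name} must be strictly positive")
        if self.sigma_g <= 0:
            raise ValueError("sigma_g must be strictly positive")
        if self.tau_act <= 0:
            raise ValueError("tau_act must be strictly positive")
        if self.theta_act <= 0:
            raise ValueError("theta_act must be strictly positive")
        if self.sigma_s < 0:
            raise ValueError("sigma_s must be non-negative")

    def tau_vectors(self, nb: int, na: int, ng: int):
        """Per-cell time-constant vectors (tau_b, tau_a, tau_g)."""
        return (
            _as_vector(self.tau_b, nb, "tau_b"),
            _as_vector(self.tau_a, na, "tau_a"),
            _as_vector(self.tau_g, ng, "tau_g"),
        )

    @property
    def tau_min(self) -> float:
        return float(
            min(
                np.min(np.asarray(self.tau_b)),
                np.min(np.asarray(self.tau_a)),
                np.min(np.asarray(self.tau_g)),
            )
        )


@dataclass(frozen=True)
class ConnectivityMatrices:
    """Signed synaptic weight matrices and optional gap junctions.

    ``w_ba[i, j]`` is the weight of the (inhibitory) synapse from A cell j
    onto B cell i, hence ``w_ba <= 0``; ``w_ab >= 0`` is the B -> A
    excitation, ``w_gb >= 0`` the B -> G pooling and ``w_ga <= 0`` the
    A -> G inhibition.  ``gap_ba[i, j] >= 0`` is the (symmetric) electric
    conductance between B cell i and A cell j; capacitances convert it to
    rate units.
    """

    w_ba: np.ndarray
    w_ab: np.ndarray
    w_gb: np.ndarray
    w_ga: np.ndarray
    gap_ba: np.ndarray | None = None
    cap_b: np.ndarray | float = 1.0
    cap_a: np.ndarray | float = 1.0

    def __post_init__(self) -> None:
        w_ba = np.asarray(self.w_ba, dtype=float)
        w_ab = np.asarray(self.w_ab, dtype=float)
        w_gb = np.asarray(self.w_gb, dtype=float)
        w_ga = np.asarray(self.w_ga, dtype=float)
        object.__setattr__(self, "w_ba", w_ba)
        object.__setattr__(self, "w_ab", w_ab)
        object.__setattr__(self, "w_gb", w_gb)
        object.__setattr__(self, "w_ga", w_ga)
        nb, na = w_ba.shape
        if w_ab.shape != (na, nb):
            raise ValueError("w_ab must have shape (NA, NB)")
        ng = w_gb.shape[0]
        if w_gb.shape != (ng, nb) or w_ga.shape != (ng, na):
            raise ValueError("w_gb / w_ga shapes inconsistent")
        if np.any(w_ba > 0):
            raise ValueError("w_ba (A -> B) must be non-positive")
        if np.any(w_ab < 0):
            raise ValueError("w_ab (B -> A) must be non-negative")
        if np.any(w_gb < 0):
            raise ValueError("w_gb (B -> G) must be non-negative")
        if np.any(w_ga > 0):
            raise ValueError("w_ga (A -> G) must be non-positive")
        if self.gap_ba is not None:
            g = np.asarray(self.gap_ba, dtype=float)
            if g.shape != (nb, na):
                raise ValueError("gap_ba must have shape (NB, NA)")
            if np.any(g < 0):
                raise ValueError("gap conductances must be non-negative")
            object.__setattr__(self, "gap_ba", g)
        if np.any(np.asarray(self.cap_b) <= 0) or np.any(np.asarray(self.cap_a) <= 0):
            raise ValueError("capacitances must be strictly positive")

    @property
    def nb(self) -> int:
        return self.w_ba.shape[0]

    @property
    def na(self) -> int:
        return self.w_ba.shape[1]

    @property
    def ng(self) -> int:
        return self.w_gb.shape[0]

    @property
    def n_total(self) -> int:
        return self.nb + self.na + self.ng

    def assemble_w(self) -> np.ndarray:
        """Full N x N chemical-synapse matrix with zero diagonal blocks."""
        nb, na, ng = self.nb, self.na, self.ng
        w = np.zeros((nb + na + ng, nb + na + ng))
        w[:nb, nb : nb + na] = self.w_ba
        w[nb : nb + na, :nb] = self.w_ab
        w[nb + na :, :nb] = self.w_gb
        w[nb + na :, nb : nb + na] = self.w_ga
        return w


@dataclass
class StateVector:
    """Concatenated network state: B voltages, A voltages, G voltages,
    optionally followed by B-cell activities (gain-control mode)."""

    x: np.ndarray
    nb: int
    na: int
    ng: int
    has_activities: bool = False

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        n = self.nb + self.na + self.ng + (self.nb if self.has_activities else 0)
        if self.x.shape != (n,):
            raise ValueError(f"state vector must have length {n}")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("state vector entries must be finite")

    @property
    def vb(self) -> np.ndarray:
        return self.x[: self.nb]

    @property
    def va(self) -> np.ndarray:
        return self.x[self.nb : self.nb + self.na]

    @property
    def vg(self) -> np.ndarray:
        return self.x[self.nb + self.na : self.nb + self.na + self.ng]

    @property
    def activities(self) -> np.ndarray:
        if not self.has_activities:
            raise AttributeError("state carries no activity variables")
        return self.x[self.nb + self.na + self.ng :]


def rectify_linear(v, theta=0.0):
    """Linear rectifier ``N(v) = v - theta`` for ``v > theta``, else 0.

    Models the silencing of a chemical synapse when the presynaptic
    voltage drops below threshold; continuous, non-negative, 1-Lipschitz.
    """
    v = np.asarray(v, dtype=float)
    out = np.where(v > theta, v - theta, 0.0)
    return float(out) if out.ndim == 0 else out


def lnp_nonlinearity(v, theta_g: float, sigma_g: float):
    """Instantaneous spiking probability of an LNP ganglion cell.

    Standard Gaussian CDF evaluated at ``(v - theta_g) / sigma_g``.
    """
    if sigma_g <= 0:
        raise ValueError("sigma_g must be strictly positive")
    v = np.asarray(v, dtype=float)
    out = ndtr((v - theta_g) / sigma_g)
    return float(out) if out.ndim == 0 else out


def gain_function(a):
    """Smooth gain-control function: 0 for a <= 0, else 1 / (1 + a**6).

    Strongly nonlinear, almost step-wise: close to 1 for small positive
    activity and dropping rapidly once the activity exceeds ~1.
    """
    a = np.asarray(a, dtype=float)
    with np.errstate(over="ignore"):
        out = np.where(a <= 0, 0.0, 1.0 / (1.0 + a**6))
    return float(out) if out.ndim == 0 else out


def binary_gain(a, theta_act: float = 2.0 / 3.0):
    """Step-function gain used by the piecewise-linear formalism.

    Returns 1 for activity in ``[0, theta_act]`` and 0 otherwise.  The
    threshold 2/3 comes from a linear interpolation of the smooth gain.
    Negative activities map to 0 like the smooth gain's off branch (they
    do not occur dynamically since the activity build-up is non-negative).
    """
    a = np.asarray(a, dtype=float)
    out = np.where((a >= 0) & (a <= theta_act), 1.0, 0.0)
    return float(out) if out.ndim == 0 else out
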