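"""Rectification domains, transport operators and event-driven integration.

Rectification of synaptic transmission partitions the phase space into
2**(NB+NA) convex domains, one per pattern of rectified B/A cells.  Inside
a domain the flow is affine, ``dX/dt = L(n) X + C(n) + F(t)``, with the
transport operator ``L(n)`` obtained from the full coupling matrix by
zeroing the output columns of rectified cells.  Trajectories are chained
across domains by locating threshold crossings (events) and restarting the
affine flow with the operator of the entered domain.

The gain-control extension appends one activity variable per B cell; with
the binary (step) gain the extended system is again piecewise linear, with
additional switching surfaces at the activity threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad_vec, solve_ivp
from scipy.linalg import expm

from .core import ConnectivityMatrices, RetinaParams
from .stimuli import DriveForcing

__all__ = [
    "DomainIndex",
    "TransportOperator",
    "Trajectory",
    "domain_of_state",
    "build_transport_operator",
    "effective_time_constants",
    "rest_state",
    "integrate_pwl",
    "integrate_gain_control",
    "segment_solution",
    "hmk_chain",
]


@dataclass(frozen=True)
class DomainIndex:
    """Rectification (and optional gain) labels identifying a linear domain.

    ``eta[alpha] = 1`` marks cell ``alpha`` (B cells first, then A cells)
    as rectified; ``gain[i] = 1`` marks B cell i as transmitting (activity
    within the gain window).  ``code`` is the binary encoding
    ``sum_alpha eta_alpha 2**(alpha-1)`` of the rectification labels.
    """

    eta: tuple[int, ...]
    gain: tuple[int, ...] | None = None

    @property
    def code(self) -> int:
        return sum(int(e) << a for a, e in enumerate(self.eta))

    @classmethod
    def from_code(cls, n: int, n_labels: int, gain=None) -> "DomainIndex":
        eta = tuple((n >> a) & 1 for a in range(n_labels))
        return cls(eta=eta, gain=None if gain is None else tuple(gain))

    @property
    def key(self):
        return (self.eta, self.gain)


def domain_of_state(
    x: np.ndarray,
    nb: int,
    na: int,
    theta_b: float,
    theta_a: float,
    activities: np.ndarray | None = None,
    theta_act: float = 2.0 / 3.0,
) -> DomainIndex:
    """Rectification/gain labels of a state.

    A cell is rectified when its voltage is strictly below its threshold
    (a cell exactly at threshold transmits zero either way, so the
    boundary assignment is a measure-zero convention).  G components are
    ignored; ``activities``, if given, yield the binary-gain labels.
    """
    x = np.asarray(x, dtype=float)
    eta_b = (x[:nb] < theta_b).astype(int)
    eta_a = (x[nb : nb + na] < theta_a).astype(int)
    gain = None
    if activities is not None:
        a = np.asarray(activities, dtype=float)
        gain = tuple(((a >= 0) & (a <= theta_act)).astype(int))
    return DomainIndex(eta=tuple(eta_b) + tuple(eta_a), gain=gain)


@dataclass
class TransportOperator:
    """Affine flow ``dX/dt = L X + C (+ F(t))`` valid inside one domain."""

    L: np.ndarray
    C: np.ndarray
    domain: DomainIndex
    nb: int
    na: int
    ng: int
    extended: bool = False

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        n = self.L.shape[0]
        if self.L.shape != (n, n) or self.C.shape != (n,):
            raise ValueError("operator dimensions inconsistent")
        cond = np.linalg.cond(self.L)
        if not np.isfinite(cond) or cond > 1e12:
            warnings.warn(
                f"transport operator nearly singular (cond={cond:.3g}); "
                "fixed points are unreliable",
                stacklevel=2,
            )

    @property
    def n(self) -> int:
        return self.L.shape[0]

    def fixed_point(self) -> np.ndarray:
        """Fixed point -L^{-1} C of the stimulus-free affine flow."""
        return -np.linalg.solve(self.L, self.C)

    def is_stable(self) -> bool:
        return bool(np.all(np.linalg.eigvals(self.L).real < 0))


def effective_time_constants(
    params: RetinaParams,
    conn: ConnectivityMatrices,
    gap_ab: np.ndarray | None = None,
):
    """Gap-junction-corrected time constants (tau_b_eff, tau_a_eff).

    ``1/tau'_Bi = 1/tau_Bi + (1/C_Bi) sum_j g_BiAj`` and the A-cell
    analogue.  Electric coupling only ever shortens time constants.  The
    conductance matrix is stored once (B rows, A columns); passing the
    A-side matrix ``gap_ab`` cross-checks the required symmetry
    ``g_BiAj = g_AjBi``.
    """
    nb, na, ng = conn.nb, conn.na, conn.ng
    tau_b, tau_a, _ = params.tau_vectors(nb, na, ng)
    if conn.gap_ba is None:
        return tau_b.copy(), tau_a.copy()
    if gap_ab is not None and not np.allclose(np.asarray(gap_ab), conn.gap_ba.T):
        raise ValueError("gap junction conductances must satisfy g_BiAj = g_AjBi")
    cap_b = np.broadcast_to(np.asarray(conn.cap_b, dtype=float), (nb,))
    cap_a = np.broadcast_to(np.asarray(conn.cap_a, dtype=float), (na,))
    inv_b = 1.0 / tau_b + conn.gap_ba.sum(axis=1) / cap_b
    inv_a = 1.0 / tau_a + conn.gap_ba.sum(axis=0) / cap_a
    return 1.0 / inv_b, 1.0 / inv_a


def build_transport_operator(
    domain: DomainIndex,
    params: RetinaParams,
    conn: ConnectivityMatrices,
    gain_control: bool = False,
) -> TransportOperator:
    """Assemble the transport operator and constant vector of a domain.

    Output columns of rectified cells are zeroed through the projectors
    ``D_B`` / ``D_A``; the constant vector collects the ``-theta`` offsets
    of the still-transmitting presynaptic cells (zero when both
    thresholds vanish).  With ``gain_control=True`` the operator is
    extended by NB activity rows, the B-output projector additionally
    zeroes gain-suppressed cells, and gap junctions (if present) add
    symmetric linear coupling plus shortened time constants.
    """
    nb, na, ng = conn.nb, conn.na, conn.ng
    n = nb + na + ng
    eta = np.asarray(domain.eta, dtype=float)
    if eta.shape != (nb + na,):
        raise ValueError("domain labels inconsistent with connectivity")
    d_b = 1.0 - eta[:nb]
    d_a = 1.0 - eta[nb:]
    tau_b_eff, tau_a_eff = effective_time_constants(params, conn)
    _, _, tau_g = params.tau_vectors(nb, na, ng)

    gap_term_b = np.zeros((nb, na))
    gap_term_a = np.zeros((na, nb))
    if conn.gap_ba is not None:
        cap_b = np.broadcast_to(np.asarray(conn.cap_b, dtype=float), (nb,))
        cap_a = np.broadcast_to(np.asarray(conn.cap_a, dtype=float), (na,))
        gap_term_b = conn.gap_ba / cap_b[:, None]
        gap_term_a = conn.gap_ba.T / cap_a[:, None]

    if not gain_control:
        L = np.zeros((n, n))
        L[:nb, :nb] = -np.diag(1.0 / tau_b_eff)
        L[:nb, nb : nb + na] = conn.w_ba * d_a[None, :] + gap_term_b
        L[nb : nb + na, :nb] = conn.w_ab * d_b[None, :] + gap_term_a
        L[nb : nb + na, nb : nb + na] = -np.diag(1.0 / tau_a_eff)
        L[nb + na :, :nb] = conn.w_gb * d_b[None, :]
        L[nb + na :, nb : nb + na] = conn.w_ga * d_a[None, :]
        L[nb + na :, nb + na :] = -np.diag(1.0 / tau_g)
        C = np.zeros(n)
        C[:nb] = -params.theta_a * (conn.w_ba @ d_a)
        C[nb : nb + na] = -params.theta_b * (conn.w_ab @ d_b)
        C[nb + na :] = -params.theta_b * (conn.w_gb @ d_b) - params.theta_a * (
            conn.w_ga @ d_a
        )
        return TransportOperator(L, C, domain, nb, na, ng, extended=False)

    if domain.gain is None:
        raise ValueError("gain-control operator requires gain labels")
    g = np.asarray(domain.gain, dtype=float)
    d_bp = d_b * g  # transmitting iff neither rectified nor gain-suppressed
    m = n + nb
    L = np.zeros((m, m))
    L[:nb, :nb] = -np.diag(1.0 / tau_b_eff)
    L[:nb, nb : nb + na] = conn.w_ba * d_a[None, :] + gap_term_b
    L[nb : nb + na, :nb] = conn.w_ab * d_bp[None, :] + gap_term_a
    L[nb : nb + na, nb : nb + na] = -np.diag(1.0 / tau_a_eff)
    L[nb + na : n, :nb] = conn.w_gb * d_bp[None, :]
    L[nb + na : n, nb : nb + na] = conn.w_ga * d_a[None, :]
    L[nb + na : n, nb + na : n] = -np.diag(1.0 / tau_g)
    L[n:, :nb] = params.h_act * np.diag(d_b)
    L[n:, n:] = -np.eye(nb) / params.tau_act
    C = np.zeros(m)
    C[:nb] = -params.theta_a * (conn.w_ba @ d_a)
    C[nb : nb + na] = -params.theta_b * (conn.w_ab @ d_bp)
    C[nb + na : n] = -params.theta_b * (conn.w_gb @ d_bp) - params.theta_a * (
        conn.w_ga @ d_a
    )
    C[n:] = -params.h_act * params.theta_b * d_b
    return TransportOperator(L, C, domain, nb, na, ng, extended=True)


def rest_state(params: RetinaParams, conn: ConnectivityMatrices) -> np.ndarray:
    """Rest state X* = -L(0)^{-1} C(0); warns if it leaves the rest domain
    or if the rest-domain operator is unstable."""
    nb, na = conn.nb, conn.na
    dom0 = DomainIndex(eta=(0,) * (nb + na))
    op = build_transport_operator(dom0, params, conn)
    x_star = op.fixed_point()
    if not op.is_stable():
        warnings.warn("rest-domain transport operator is unstable", stacklevel=2)
    dom_star = domain_of_state(x_star, nb, na, params.theta_b, params.theta_a)
    if dom_star.code != 0:
        warnings.warn(
            "rest state falls outside the non-rectified domain; dynamics may "
            "settle on a different attractor",
            stacklevel=2,
        )
    return x_star


@dataclass
class Trajectory:
    """Sampled piecewise-linear trajectory with its domain-crossing events."""

    ts: np.ndarray
    xs: np.ndarray  # (n_samples, n_state)
    events: list = field(default_factory=list)  # (t, code_before, code_after, state)
    segments: list = field(default_factory=list)  # (t_start, t_end, DomainIndex)
    nb: int = 0
    na: int = 0
    ng: int = 0
    extended: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def vb(self) -> np.ndarray:
        return self.xs[:, : self.nb]

    @property
    def va(self) -> np.ndarray:
        return self.xs[:, self.nb : self.nb + self.na]

    @property
    def vg(self) -> np.ndarray:
        return self.xs[:, self.nb + self.na : self.nb + self.na + self.ng]

    @property
    def activities(self) -> np.ndarray:
        if not self.extended:
            raise AttributeError("trajectory carries no activity variables")
        return self.xs[:, self.nb + self.na + self.ng :]

    @property
    def n_events(self) -> int:
        return len(self.events)

    def state_at(self, t: float) -> np.ndarray:
        """Linear interpolation of the sampled trajectory."""
        return np.array(
            [np.interp(t, self.ts, self.xs[:, j]) for j in range(self.xs.shape[1])]
        )


def _crossing_events(op: TransportOperator, params: RetinaParams):
    """Terminal event functions for every switching surface of a domain."""
    nb, na = op.nb, op.na
    eta = op.domain.eta
    thresholds = [params.theta_b] * nb + [params.theta_a] * na
    fns = []
    for idx in range(nb + na):
        # a rectified cell (below threshold) can only exit upward and
        # vice versa; the direction filter plus a tiny voltage hysteresis
        # suppress spurious re-triggers when the state sits exactly on a
        # switching surface (e.g. the all-zero rest state with vanishing
        # thresholds before stimulus onset).
        th = thresholds[idx]
        eps = 1e-11 * max(1.0, abs(th))
        sgn = 1.0 if eta[idx] else -1.0
        def ev(t, y, i=idx, th=th, off=sgn * eps):
            return y[i] - th - off
        ev.terminal = True
        ev.direction = sgn
        fns.append(ev)
    if op.extended:
        n_volt = op.nb + op.na + op.ng
        gain = op.domain.gain
        th_a = params.theta_act
        eps_a = 1e-11 * max(1.0, abs(th_a))
        for j in range(op.nb):
            sgn = 1.0 if gain[j] else -1.0
            def ev_a(t, y, i=n_volt + j, th=th_a, off=sgn * eps_a):
                return y[i] - th - off
            ev_a.terminal = True
            ev_a.direction = sgn
            fns.append(ev_a)
    return fns


def _integrate_event_driven(
    x0,
    forcing,
    tspan,
    params,
    conn,
    *,
    gain_control,
    t_eval,
    event_tol,
    max_step,
    rtol,
    atol,
    max_events,
    method,
):
    nb, na, ng = conn.nb, conn.na, conn.ng
    n_volt = nb + na + ng
    x = np.asarray(x0, dtype=float).copy()
    if not np.all(np.isfinite(x)):
        raise ValueError("initial state must be finite")
    t0, t1 = float(tspan[0]), float(tspan[1])
    if t_eval is None:
        t_eval = np.linspace(t0, t1, 1001)
    t_eval = np.asarray(t_eval, dtype=float)
    if event_tol is None:
        event_tol = 1e-9 * params.tau_min

    def current_domain(state):
        acts = state[n_volt:] if gain_control else None
        return domain_of_state(
            state, nb, na, params.theta_b, params.theta_a,
            activities=acts, theta_act=params.theta_act,
        )

    op_cache: dict = {}

    def get_op(dom):
        if dom.key not in op_cache:
            op_cache[dom.key] = build_transport_operator(
                dom, params, conn, gain_control=gain_control
            )
        return op_cache[dom.key]

    domain = current_domain(x)
    t = t0
    events_out = []
    segments = []
    sample_ts: list[np.ndarray] = []
    sample_xs: list[np.ndarray] = []

    if forcing is not None and gain_control:
        base_forcing = forcing

        def forcing(s, _f=base_forcing, _nb=nb):  # pad with activity zeros
            fv = np.asarray(_f(s), dtype=float)
            return np.concatenate([fv, np.zeros(n_volt + _nb - len(fv))])

    while t < t1 - 1e-14 * max(1.0, abs(t1)):
        op = get_op(domain)
        if forcing is None:
            def rhs(s, y, L=op.L, c=op.C):
                return L @ y + c
        else:
            def rhs(s, y, L=op.L, c=op.C, f=forcing):
                return L @ y + c + f(s)
        ev_fns = _crossing_events(op, params)
        sol = solve_ivp(
            rhs,
            (t, t1),
            x,
            method=method,
            events=ev_fns,
            dense_output=True,
            rtol=rtol,
            atol=atol,
            max_step=max_step,
        )
        if sol.status == -1:
            raise RuntimeError(f"integration failed in domain {domain.code}: "
                               f"{sol.message}")
        t_end = float(sol.t[-1])
        x_end = sol.y[:, -1]
        if not np.all(np.isfinite(x_end)):
            raise RuntimeError(
                f"non-finite state at t={t_end} in domain {domain.code}"
            )
        mask = (t_eval >= t - 1e-12) & (t_eval <= t_end + 1e-12)
        if np.any(mask):
            pts = np.clip(t_eval[mask], sol.t[0], sol.t[-1])
            sample_ts.append(t_eval[mask])
            sample_xs.append(sol.sol(pts).T)
            # avoid double-sampling boundary points in the next segment
            t_eval = t_eval[~mask]
        segments.append((t, t_end, domain))
        if sol.status == 1:
            flipped = []
            for i, te in enumerate(sol.t_events):
                if len(te) and abs(te[-1] - t_end) <= event_tol:
                    flipped.append(i)
            if not flipped:
                raise RuntimeError("terminal event reported but none located")
            eta = list(domain.eta)
            gain = None if domain.gain is None else list(domain.gain)
            for i in flipped:
                if i < nb + na:
                    eta[i] = 1 - eta[i]
                else:
                    gain[i - (nb + na)] = 1 - gain[i - (nb + na)]
            new_domain = DomainIndex(
                eta=tuple(eta), gain=None if gain is None else tuple(gain)
            )
            events_out.append((t_end, domain.code, new_domain.code, x_end.copy()))
            if len(events_out) > max_events:
                raise RuntimeError(
                    f"more than {max_events} crossing events; trajectory "
                    "appears to chatter (consider the stochastic scheme)"
                )
            domain = new_domain
        t = t_end
        x = x_end

    ts = np.concatenate(sample_ts) if sample_ts else np.array([t0])
    xs = np.vstack(sample_xs) if sample_xs else x[None, :]
    order = np.argsort(ts, kind="stable")
    return Trajectory(
        ts=ts[order],
        xs=xs[order],
        events=events_out,
        segments=segments,
        nb=nb,
        na=na,
        ng=ng,
        extended=gain_control,
        meta={
            "event_tol": event_tol,
            "rtol": rtol,
            "atol": atol,
            "stochastic": False,
        },
    )


def _integrate_stochastic(
    x0, forcing, tspan, params, conn, *, gain_control, t_eval, max_step, seed
):
    """Fixed-step Euler-Maruyama with per-step domain re-evaluation.

    White-noise paths cross switching surfaces densely, so exact event
    location is ill-posed; domains are simply re-read each step.
    """
    nb, na, ng = conn.nb, conn.na, conn.ng
    n_volt = nb + na + ng
    x = np.asarray(x0, dtype=float).copy()
    t0, t1 = float(tspan[0]), float(tspan[1])
    dt = min(max_step, params.tau_min / 50.0)
    n_steps = int(np.ceil((t1 - t0) / dt))
    dt = (t1 - t0) / n_steps
    rng = np.random.default_rng(seed)
    sigma = forcing.sigma_s
    mask = forcing.noise_mask()
    if gain_control:
        mask = np.concatenate([mask, np.zeros(nb)])
    ts = t0 + dt * np.arange(n_steps + 1)
    xs = np.empty((n_steps + 1, len(x)))
    xs[0] = x
    op_cache: dict = {}
    segments = []
    seg_start, seg_dom = t0, None
    sqdt = np.sqrt(dt)
    for k in range(n_steps):
        acts = x[n_volt:] if gain_control else None
        dom = domain_of_state(
            x, nb, na, params.theta_b, params.theta_a,
            activities=acts, theta_act=params.theta_act,
        )
        if seg_dom is None:
            seg_dom = dom
        elif dom.key != seg_dom.key:
            segments.append((seg_start, ts[k], seg_dom))
            seg_start, seg_dom = ts[k], dom
        if dom.key not in op_cache:
            op_cache[dom.key] = build_transport_operator(
                dom, params, conn, gain_control=gain_control
            )
        op = op_cache[dom.key]
        drift = op.L @ x + op.C + forcing.mean(ts[k])[: len(x)] if not gain_control \
            else op.L @ x + op.C + np.concatenate([forcing.mean(ts[k]), np.zeros(nb)])
        x = x + dt * drift + sigma * sqdt * mask * rng.standard_normal(len(x))
        xs[k + 1] = x
    segments.append((seg_start, t1, seg_dom))
    if t_eval is not None:
        t_eval = np.asarray(t_eval, dtype=float)
        xs = np.column_stack(
            [np.interp(t_eval, ts, xs[:, j]) for j in range(xs.shape[1])]
        )
        ts = t_eval
    return Trajectory(
        ts=ts,
        xs=xs,
        events=[],
        segments=segments,
        nb=nb,
        na=na,
        ng=ng,
        extended=gain_control,
        meta={"stochastic": True, "seed": seed, "dt": dt},
    )


def integrate_pwl(
    x0,
    forcing,
    tspan,
    params: RetinaParams,
    conn: ConnectivityMatrices,
    *,
    t_eval=None,
    event_tol: float | None = None,
    max_step: float = np.inf,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    max_events: int = 100_000,
    method: str = "LSODA",
    seed: int | None = None,
) -> Trajectory:
    """Event-driven integration of the piecewise-linear network dynamics.

    Within a domain the affine flow is advanced by a stiff-capable
    adaptive solver; threshold crossings are located by the solver's root
    finder (well below ``event_tol`` in time), the crossing cells' labels
    are flipped — simultaneously-crossing cells in a single event — and
    integration restarts with the new transport operator.

    If ``forcing`` is a :class:`~retinet.stimuli.WhiteNoiseForcing` with
    positive intensity, a fixed-step Euler-Maruyama scheme with per-step
    domain re-evaluation is used instead and ``seed`` (or the forcing's
    seed) drives the noise stream.
    """
    sigma = getattr(forcing, "sigma_s", 0.0)
    if sigma and sigma > 0:
        return _integrate_stochastic(
            x0, forcing, tspan, params, conn,
            gain_control=False, t_eval=t_eval, max_step=max_step,
            seed=seed if seed is not None else forcing.seed,
        )
    return _integrate_event_driven(
        x0, forcing, tspan, params, conn,
        gain_control=False, t_eval=t_eval, event_tol=event_tol,
        max_step=max_step, rtol=rtol, atol=atol,
        max_events=max_events, method=method,
    )


def integrate_gain_control(
    x0,
    forcing,
    tspan,
    params: RetinaParams,
    conn: ConnectivityMatrices,
    *,
    t_eval=None,
    event_tol: float | None = None,
    max_step: float = np.inf,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    max_events: int = 100_000,
    method: str = "LSODA",
    seed: int | None = None,
) -> Trajectory:
    """Event-driven integration of the binary-gain extended system.

    The state is ``(V_B, V_A, V_G, a)``; switching surfaces are the
    voltage thresholds and the activity threshold ``theta_act``.  The
    smooth-gain system is deliberately *not* handled here: it is genuinely
    nonlinear and serves as the reference oracle
    (:func:`retinet.reference.reference_trajectory`).
    """
    sigma = getattr(forcing, "sigma_s", 0.0)
    if sigma and sigma > 0:
        return _integrate_stochastic(
            x0, forcing, tspan, params, conn,
            gain_control=True, t_eval=t_eval, max_step=max_step,
            seed=seed if seed is not None else forcing.seed,
        )
    return _integrate_event_driven(
        x0, forcing, tspan, params, conn,
        gain_control=True, t_eval=t_eval, event_tol=event_tol,
        max_step=max_step, rtol=rtol, atol=atol,
        max_events=max_events, method=method,
    )


def _pl_forcing_convolution(L, C, forcing, a, b, n_state):
    """Exact ``int_a^b exp(L (b - s)) (C + F(s)) ds`` for piecewise-linear F.

    The forcing of a :class:`~retinet.stimuli.DriveForcing` is linear
    between master-grid samples, so the convolution is integrated in
    closed form on every sub-interval (endpoint-weight matrices built
    from ``int exp(L u) du`` and ``int u exp(L u) du``); the only error
    left is the matrix-exponential round-off.
    """
    ts = forcing.ts
    inner = ts[(ts > a + 1e-12) & (ts < b - 1e-12)]
    nodes = np.concatenate([[a], inner, [b]])
    phi = np.zeros(n_state)
    eye = np.eye(n_state)
    cache: dict = {}

    def pad(f):
        f = np.asarray(f, dtype=float)
        if len(f) < n_state:
            f = np.concatenate([f, np.zeros(n_state - len(f))])
        return C + f

    for s0, s1 in zip(nodes[:-1], nodes[1:]):
        hh = s1 - s0
        if hh <= 1e-15:
            continue
        key = round(hh, 12)
        if key not in cache:
            E = expm(L * hh)
            I1 = np.linalg.solve(L, E - eye)
            I2 = np.linalg.solve(L, hh * E - I1)
            cache[key] = (E, I2 / hh, I1 - I2 / hh)
        E, M0, M1 = cache[key]
        f0, f1 = forcing.interval_endpoint_values(s0, s1)
        phi = E @ phi + M0 @ pad(f0) + M1 @ pad(f1)
    return phi


def segment_solution(
    L: np.ndarray,
    x_in: np.ndarray,
    t_in: float,
    t: float,
    forcing=None,
    C: np.ndarray | None = None,
    tol: float = 1e-12,
) -> np.ndarray:
    """Within-domain solution: matrix-exponential propagation plus the
    forcing convolution ``int exp(L (t - s)) (C + F(s)) ds``.

    Constant forcing uses the closed form through the affine fixed point;
    time-varying forcing is integrated by adaptive vector quadrature.
    """
    L = np.asarray(L, dtype=float)
    x_in = np.asarray(x_in, dtype=float)
    if t < t_in:
        raise ValueError("t must be >= t_in")
    prop = expm(L * (t - t_in)) @ x_in
    if forcing is None:
        if C is None or not np.any(C):
            return prop
        x_star = -np.linalg.solve(L, C)
        return x_star + expm(L * (t - t_in)) @ (x_in - x_star)
    if isinstance(forcing, DriveForcing):
        c = np.zeros(L.shape[0]) if C is None else np.asarray(C, dtype=float)
        return prop + _pl_forcing_convolution(L, c, forcing, t_in, t, L.shape[0])
    def integrand(s):
        f = np.asarray(forcing(s), dtype=float)
        if C is not None:
            f = f + C
        return expm(L * (t - s)) @ f
    integral, _ = quad_vec(integrand, t_in, t, epsabs=tol, epsrel=tol)
    return prop + integral


def hmk_chain(
    traj: Trajectory,
    params: RetinaParams,
    conn: ConnectivityMatrices,
    forcing=None,
    tol: float = 1e-12,
):
    """Reconstruct domain-entry states from the transport-operator chain.

    For a trajectory visiting domains ``n_1, ..., n_K``, the state at the
    exit of domain ``n_k`` is ``sum_{m=0}^{k} H_m^k Phi_m`` where
    ``Phi_0`` is the initial state, ``Phi_m`` integrates the forcing over
    the m-th segment propagated to that segment's exit, and ``H_m^k``
    (built by the recursion ``H_k^k = I``,
    ``H_{k-1}^k = exp(L(n_k) dur_k)``, ``H_m^k = H_{k-1}^k H_m^{k-1}``)
    transports exit states forward.  The operators do not commute, so the
    order of the products matters.

    Returns ``(times, states)``: the exit time and reconstructed state of
    every visited domain; they must match the integrated trajectory.
    """
    if not traj.segments:
        raise ValueError("trajectory has no segments")
    gain_control = traj.extended
    ops = [
        build_transport_operator(dom, params, conn, gain_control=gain_control)
        for (_, _, dom) in traj.segments
    ]
    x0 = traj.xs[0]
    if abs(traj.ts[0] - traj.segments[0][0]) > 1e-9:
        raise ValueError("trajectory samples do not start at the first segment")
    phis = [x0]
    for (a, b, _), op in zip(traj.segments, ops):
        if isinstance(forcing, DriveForcing):
            phi = _pl_forcing_convolution(op.L, op.C, forcing, a, b, op.n)
        else:
            def integrand(s, op=op, b=b):
                f = op.C.copy()
                if forcing is not None:
                    fv = np.asarray(forcing(s), dtype=float)
                    if len(fv) < op.n:  # extended state: forcing on voltages
                        f = f + np.concatenate([fv, np.zeros(op.n - len(fv))])
                    else:
                        f = f + fv
                return expm(op.L * (b - s)) @ f
            phi, _ = quad_vec(integrand, a, b, epsabs=tol, epsrel=tol)
        phis.append(phi)

    n_seg = len(traj.segments)
    times = []
    states = []
    # H[m] holds H_m^k for the current k
    H = [np.eye(ops[0].n)]
    for k in range(1, n_seg + 1):
        a, b, _ = traj.segments[k - 1]
        step = expm(ops[k - 1].L * (b - a))
        H = [step @ h for h in H] + [np.eye(ops[0].n)]
        state = sum(H[m] @ phis[m] for m in range(k + 1))
        times.append(b)
        states.append(state)
    return np.array(times), np.array(states)
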