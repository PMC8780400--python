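"""Brute-force reference paths used to cross-check the event-driven solver.

These routines integrate the *nonlinear* right-hand side directly — the
rectifiers (and, optionally, the smooth or binary gain) are evaluated
pointwise, with no domain bookkeeping, no transport operators and no event
location.  They are deliberately independent of the piecewise-linear
machinery so that agreement between the two is informative.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .core import (
    ConnectivityMatrices,
    RetinaParams,
    binary_gain,
    gain_function,
    rectify_linear,
)
from .dynamics import effective_time_constants

__all__ = ["nonlinear_rhs", "reference_trajectory", "transfer_function"]


def nonlinear_rhs(
    params: RetinaParams,
    conn: ConnectivityMatrices,
    forcing=None,
    gain_control: bool = False,
    gain: str = "smooth",
):
    """Right-hand side of the full nonlinear network ODE.

    Synaptic outputs pass through the linear rectifier; with
    ``gain_control`` the B-cell outputs toward A and G cells are further
    multiplied by the gain of the activity variable (``"smooth"`` for the
    1/(1+a^6) form, ``"binary"`` for the step function).
    """
    nb, na, ng = conn.nb, conn.na, conn.ng
    tau_b_eff, tau_a_eff = effective_time_constants(params, conn)
    _, _, tau_g = params.tau_vectors(nb, na, ng)
    gap_b = gap_a = None
    if conn.gap_ba is not None:
        cap_b = np.broadcast_to(np.asarray(conn.cap_b, dtype=float), (nb,))
        cap_a = np.broadcast_to(np.asarray(conn.cap_a, dtype=float), (na,))
        gap_b = conn.gap_ba / cap_b[:, None]
        gap_a = conn.gap_ba.T / cap_a[:, None]
    gain_fn = gain_function if gain == "smooth" else (
        lambda a: binary_gain(a, params.theta_act)
    )

    def rhs(t, x):
        vb = x[:nb]
        va = x[nb : nb + na]
        vg = x[nb + na : nb + na + ng]
        rb = rectify_linear(vb, params.theta_b)
        ra = rectify_linear(va, params.theta_a)
        if gain_control:
            acts = x[nb + na + ng :]
            rb_gated = rb * gain_fn(acts)
        else:
            rb_gated = rb
        f = np.zeros(nb + na + ng)
        if forcing is not None:
            f = np.asarray(forcing(t), dtype=float)
        dvb = -vb / tau_b_eff + conn.w_ba @ ra + f[:nb]
        dva = -va / tau_a_eff + conn.w_ab @ rb_gated + f[nb : nb + na]
        dvg = -vg / tau_g + conn.w_gb @ rb_gated + conn.w_ga @ ra + f[nb + na :]
        if gap_b is not None:
            dvb = dvb + gap_b @ va
            dva = dva + gap_a @ vb
        if not gain_control:
            return np.concatenate([dvb, dva, dvg])
        dact = -acts / params.tau_act + params.h_act * rb
        return np.concatenate([dvb, dva, dvg, dact])

    return rhs


def reference_trajectory(
    x0,
    forcing,
    tspan,
    params: RetinaParams,
    conn: ConnectivityMatrices,
    t_eval,
    gain_control: bool = False,
    gain: str = "smooth",
    rtol: float = 1e-10,
    atol: float = 1e-12,
    max_step: float = np.inf,
):
    """Dense adaptive integration of the nonlinear system; returns the
    state sampled at ``t_eval`` as an (n_samples, n_state) array."""
    rhs = nonlinear_rhs(params, conn, forcing, gain_control, gain)
    sol = solve_ivp(
        rhs,
        (float(tspan[0]), float(tspan[1])),
        np.asarray(x0, dtype=float),
        t_eval=np.asarray(t_eval, dtype=float),
        rtol=rtol,
        atol=atol,
        max_step=max_step,
        method="LSODA",
    )
    if not sol.success:
        raise RuntimeError(f"reference integration failed: {sol.message}")
    return sol.y.T


def transfer_function(L: np.ndarray, input_pattern: np.ndarray, readout: int, omega):
    """Linear-systems frequency response ``|e_r^T (i w I - L)^{-1} p|``.

    Independent oracle for resonance scans: the steady-state amplitude of
    the readout component under sinusoidal forcing along ``input_pattern``
    at angular frequency ``omega`` (rad/ms).
    """
    L = np.asarray(L, dtype=float)
    p = np.asarray(input_pattern, dtype=complex)
    omegas = np.atleast_1d(np.asarray(omega, dtype=float))
    n = L.shape[0]
    out = np.empty(len(omegas))
    for k, w in enumerate(omegas):
        resp = np.linalg.solve(1j * w * np.eye(n) - L, p)
        out[k] = abs(resp[readout])
    return out[0] if np.ndim(omega) == 0 else out
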