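"""Rectification domains, transport operators and event-driven integration."""

import numpy as np
import pytest

from retinet import (
    ConnectivityMatrices,
    RetinaParams,
    build_transport_operator,
    domain_of_state,
    effective_time_constants,
    hmk_chain,
    integrate_gain_control,
    integrate_pwl,
    rest_state,
    segment_solution,
)
from retinet.core import rectify_linear
from retinet.dynamics import DomainIndex
from retinet.fixtures import random_stable_network
from retinet.reference import nonlinear_rhs, reference_trajectory
from retinet.stimuli import WhiteNoiseForcing


class TestDomainIndex:
    def test_binary_coding_examples(self):
        nb, na = 3, 2
        # all above threshold: rest domain
        x = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 0.0])
        assert domain_of_state(x, nb, na, 0.0, 0.0).code == 0
        # only B cell 1 rectified -> n = 1; B cells 1 and 2 -> n = 3
        x1 = x.copy(); x1[0] = -0.5
        assert domain_of_state(x1, nb, na, 0.0, 0.0).code == 1
        x3 = x1.copy(); x3[1] = -0.5
        assert domain_of_state(x3, nb, na, 0.0, 0.0).code == 3
        # only A cell 1 rectified -> n = 2**NB
        xa = x.copy(); xa[nb] = -0.5
        assert domain_of_state(xa, nb, na, 0.0, 0.0).code == 2**nb

    @pytest.mark.parametrize("code", [0, 1, 5, 17, 31])
    def test_code_roundtrip(self, code):
        dom = DomainIndex.from_code(code, 5)
        assert dom.code == code

    def test_boundary_assignment(self):
        # exactly at threshold: not rectified (transmits zero either way)
        x = np.array([0.5, 0.5, 0.2])
        dom = domain_of_state(x, 2, 1, 0.5, 0.2)
        assert dom.eta == (0, 0, 0)

    def test_gain_labels(self):
        dom = domain_of_state(
            np.zeros(4), 2, 1, -1.0, -1.0,
            activities=np.array([0.3, 0.9]), theta_act=2 / 3,
        )
        assert dom.gain == (1, 0)


class TestTransportOperator:
    def test_fully_rectified_domain_is_pure_leak(self, small_network):
        params, conn = small_network
        nb, na, ng = conn.nb, conn.na, conn.ng
        dom = DomainIndex(eta=(1,) * (nb + na))
        op = build_transport_operator(dom, params, conn)
        tb, ta, tg = params.tau_vectors(nb, na, ng)
        expected = -np.concatenate([1 / tb, 1 / ta, 1 / tg])
        lam = np.sort(np.linalg.eigvals(op.L).real)
        assert np.allclose(np.sort(expected), lam, atol=1e-12)
        # rectified cell alpha: canonical eigenvector
        e0 = np.zeros(op.n); e0[0] = 1.0
        assert np.allclose(op.L @ e0, -e0 / tb[0])

    def test_zero_thresholds_zero_constant(self, small_network):
        _, conn = small_network
        params = RetinaParams(theta_b=0.0, theta_a=0.0)
        for code in (0, 3, 17, 63):
            dom = DomainIndex.from_code(code, conn.nb + conn.na)
            op = build_transport_operator(dom, params, conn)
            assert np.all(op.C == 0)

    def test_rest_domain_matches_entrywise_jacobian(self):
        """Spectrum of the assembled L(0) equals that of the Jacobian of
        the nonlinear right-hand side, built independently by finite
        differences in the non-rectified regime."""
        params, conn = random_stable_network(3, 2, 1, seed=7)
        params = RetinaParams(
            tau_b=params.tau_b, tau_a=params.tau_a, tau_g=params.tau_g,
            theta_b=-10.0, theta_a=-10.0,
        )
        n = conn.n_total
        dom = DomainIndex(eta=(0,) * (conn.nb + conn.na))
        op = build_transport_operator(dom, params, conn)
        rhs = nonlinear_rhs(params, conn)
        x0 = np.zeros(n)  # far above the (negative) thresholds
        eps = 1e-6
        jac = np.empty((n, n))
        for j in range(n):
            dx = np.zeros(n); dx[j] = eps
            jac[:, j] = (rhs(0.0, x0 + dx) - rhs(0.0, x0 - dx)) / (2 * eps)
        assert np.allclose(
            np.sort_complex(np.linalg.eigvals(op.L)),
            np.sort_complex(np.linalg.eigvals(jac)),
            atol=1e-5,
        )

    def test_constant_vector_against_nonlinear_rhs(self, small_network):
        """C(n) + L(n) x must reproduce the nonlinear right-hand side at
        any interior point of the domain, for every domain."""
        params, conn = small_network
        rhs = nonlinear_rhs(params, conn)
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.uniform(-1, 1, conn.n_total)
            dom = domain_of_state(x, conn.nb, conn.na, params.theta_b, params.theta_a)
            op = build_transport_operator(dom, params, conn)
            assert np.allclose(op.L @ x + op.C, rhs(0.0, x), atol=1e-12)


class TestGapJunctions:
    def test_zero_conductance_leaves_tau(self, small_network):
        params, conn = small_network
        tb, ta = effective_time_constants(params, conn)
        tb0, ta0, _ = params.tau_vectors(conn.nb, conn.na, conn.ng)
        assert np.allclose(tb, tb0) and np.allclose(ta, ta0)

    def test_single_junction_formula(self):
        conn = ConnectivityMatrices(
            w_ba=-np.zeros((1, 1)), w_ab=np.zeros((1, 1)),
            w_gb=np.ones((1, 1)), w_ga=-np.zeros((1, 1)),
            gap_ba=np.array([[0.3]]), cap_b=1.0, cap_a=2.0,
        )
        params = RetinaParams(tau_b=10.0, tau_a=10.0, tau_g=5.0)
        tb, ta = effective_time_constants(params, conn)
        assert 1 / tb[0] == pytest.approx(0.1 + 0.3)
        assert 1 / ta[0] == pytest.approx(0.1 + 0.15)

    def test_gap_junctions_shorten_time_constants(self):
        rng = np.random.default_rng(4)
        gap = np.abs(rng.normal(size=(3, 2)))
        conn = ConnectivityMatrices(
            w_ba=-np.abs(rng.normal(size=(3, 2))),
            w_ab=np.abs(rng.normal(size=(2, 3))),
            w_gb=np.abs(rng.normal(size=(1, 3))),
            w_ga=-np.abs(rng.normal(size=(1, 2))),
            gap_ba=gap,
        )
        params = RetinaParams(tau_b=12.0, tau_a=8.0)
        tb, ta = effective_time_constants(params, conn)
        assert np.all(tb <= 12.0 + 1e-12) and np.all(ta <= 8.0 + 1e-12)

    def test_asymmetric_gap_spec_rejected(self, small_network):
        params, conn = small_network
        conn_g = ConnectivityMatrices(
            w_ba=conn.w_ba, w_ab=conn.w_ab, w_gb=conn.w_gb, w_ga=conn.w_ga,
            gap_ba=np.full((conn.nb, conn.na), 0.1),
        )
        with pytest.raises(ValueError):
            effective_time_constants(
                params, conn_g, gap_ab=np.full((conn.na, conn.nb), 0.2)
            )


class TestIntegration:
    def test_rest_state_is_fixed_point(self, small_network):
        params, conn = small_network
        with pytest.warns(UserWarning):
            x_star = rest_state(params, conn)
        traj = integrate_pwl(x_star, None, (0, 100), params, conn,
                            t_eval=np.linspace(0, 100, 11))
        # the rest state of L(0) is a fixed point while the trajectory
        # stays in the rest domain
        dom0 = DomainIndex(eta=(0,) * (conn.nb + conn.na))
        op = build_transport_operator(dom0, params, conn)
        if domain_of_state(x_star, conn.nb, conn.na,
                           params.theta_b, params.theta_a).code == 0:
            assert np.abs(traj.xs - x_star).max() < 1e-8

    def test_matches_dense_nonlinear_oracle(self, small_network, flash_forcing):
        params, conn = small_network
        t_eval = np.linspace(0, 300, 601)
        traj = integrate_pwl(np.zeros(conn.n_total), flash_forcing, (0, 300),
                            params, conn, t_eval=t_eval)
        ref = reference_trajectory(np.zeros(conn.n_total), flash_forcing,
                                   (0, 300), params, conn, t_eval)
        assert traj.n_events >= 2
        assert np.abs(traj.xs - ref).max() < 1e-5

    def test_return_to_rest_from_rectified_states(self):
        """Zero stimulus: trajectories started in rectified domains come
        back to the rest domain and converge to the rest state."""
        params, conn = random_stable_network(3, 2, 1, seed=13, coupling=0.015)
        params = RetinaParams(
            tau_b=params.tau_b, tau_a=params.tau_a, tau_g=params.tau_g,
            theta_b=-1.0, theta_a=-1.0,
        )
        x_star = rest_state(params, conn)
        assert domain_of_state(x_star, conn.nb, conn.na, -1.0, -1.0).code == 0
        rng = np.random.default_rng(2)
        t_end = 50 * float(np.max([params.tau_b, params.tau_a, params.tau_g]))
        for _ in range(5):
            x0 = x_star - rng.uniform(0.5, 2.0, conn.n_total)
            traj = integrate_pwl(x0, None, (0, t_end), params, conn,
                                t_eval=np.array([0.0, t_end]))
            assert np.linalg.norm(traj.xs[-1] - x_star) < 1e-6
            assert traj.segments[-1][2].code == 0

    def test_skew_product_structure(self, small_network, flash_forcing):
        """Perturbing ganglion-cell initial voltages leaves the B/A
        trajectories bit-identical: no feedback from the output layer."""
        params, conn = small_network
        nb, na = conn.nb, conn.na
        t_eval = np.linspace(0, 120, 121)
        x0 = np.zeros(conn.n_total)
        x1 = x0.copy(); x1[nb + na:] += 3.0
        tr0 = integrate_pwl(x0, flash_forcing, (0, 120), params, conn, t_eval=t_eval)
        tr1 = integrate_pwl(x1, flash_forcing, (0, 120), params, conn, t_eval=t_eval)
        # identical up to the solver's error-control coupling: the G
        # components only influence adaptive step selection, never the
        # B/A flow itself
        assert np.abs(tr0.xs[:, :nb + na] - tr1.xs[:, :nb + na]).max() < 1e-8
        assert [s_[2].code for s_ in tr0.segments] == [s_[2].code for s_ in tr1.segments]

    def test_nonfinite_initial_state_rejected(self, small_network):
        params, conn = small_network
        x0 = np.zeros(conn.n_total); x0[0] = np.inf
        with pytest.raises(ValueError):
            integrate_pwl(x0, None, (0, 10), params, conn)


class TestSegmentSolution:
    def test_pure_exponential_when_unforced(self):
        rng = np.random.default_rng(5)
        L = -np.eye(3) * 0.2 + 0.01 * rng.normal(size=(3, 3))
        x0 = rng.normal(size=3)
        from scipy.linalg import expm
        assert np.allclose(segment_solution(L, x0, 0.0, 7.0),
                           expm(7.0 * L) @ x0)

    def test_constant_forcing_reaches_affine_fixed_point(self):
        L = np.diag([-0.5, -0.25])
        C = np.array([1.0, 2.0])
        x_inf = segment_solution(L, np.zeros(2), 0.0, 200.0, C=C)
        assert np.allclose(x_inf, -np.linalg.solve(L, C), atol=1e-10)

    def test_time_varying_forcing_matches_linear_ode_oracle(self):
        from scipy.integrate import solve_ivp
        rng = np.random.default_rng(8)
        L = -np.eye(4) * 0.3 + 0.05 * rng.normal(size=(4, 4))
        f = lambda t: np.array([np.sin(0.3 * t), np.cos(0.2 * t), 0.1 * t % 1.0, 0.0])
        x0 = rng.normal(size=4)
        got = segment_solution(L, x0, 0.0, 12.0, forcing=f, tol=1e-12)
        sol = solve_ivp(lambda t, y: L @ y + f(t), (0, 12), x0,
                        rtol=1e-11, atol=1e-13)
        assert np.abs(got - sol.y[:, -1]).max() < 1e-8


class TestHmkChain:
    def test_single_segment_reduces_to_segment_solution(self, small_network):
        params, conn = small_network
        x0 = np.full(conn.n_total, 5.0)  # far inside the rest domain
        traj = integrate_pwl(x0, None, (0, 2), params, conn,
                            t_eval=np.linspace(0, 2, 21))
        assert traj.n_events == 0
        times, states = hmk_chain(traj, params, conn, None)
        dom0 = traj.segments[0][2]
        op = build_transport_operator(dom0, params, conn)
        direct = segment_solution(op.L, x0, 0.0, 2.0, C=op.C)
        assert np.allclose(states[-1], direct, atol=1e-9)

    def test_chain_identity_at_every_domain_entry(self, small_network, flash_forcing):
        params, conn = small_network
        traj = integrate_pwl(np.zeros(conn.n_total), flash_forcing, (0, 300),
                            params, conn, method="DOP853",
                            rtol=1e-12, atol=1e-14)
        assert traj.n_events >= 2
        _, states = hmk_chain(traj, params, conn, flash_forcing)
        for (t_ev, _, _, x_ev), s in zip(traj.events, states):
            assert np.abs(s - x_ev).max() < 1e-8

    def test_operators_do_not_commute(self, small_network, flash_forcing):
        from scipy.linalg import expm
        params, conn = small_network
        traj = integrate_pwl(np.zeros(conn.n_total), flash_forcing, (0, 300),
                            params, conn)
        doms = [seg[2] for seg in traj.segments[:2]]
        ops = [build_transport_operator(d, params, conn) for d in doms]
        a = expm(ops[0].L) @ expm(ops[1].L)
        b = expm(ops[1].L) @ expm(ops[0].L)
        assert not np.allclose(a, b)


class TestGainControl:
    def _network(self):
        params0, conn = random_stable_network(3, 2, 1, seed=11)
        params = RetinaParams(
            tau_b=params0.tau_b, tau_a=params0.tau_a, tau_g=params0.tau_g,
            theta_b=0.05, theta_a=0.0, tau_act=50.0, h_act=0.05,
        )
        return params, conn

    def test_h_zero_reduces_to_plain_dynamics(self, flash_forcing):
        params0, conn = random_stable_network(3, 2, 1, seed=11)
        params = RetinaParams(
            tau_b=params0.tau_b, tau_a=params0.tau_a, tau_g=params0.tau_g,
            theta_b=0.05, theta_a=0.0, tau_act=50.0, h_act=0.0,
        )
        forcing = _scaled_forcing(conn, params)
        t_eval = np.linspace(0, 200, 201)
        x0 = np.zeros(conn.n_total + conn.nb)
        tg = integrate_gain_control(x0, forcing, (0, 200), params, conn, t_eval=t_eval)
        tp = integrate_pwl(np.zeros(conn.n_total), forcing, (0, 200), params, conn,
                          t_eval=t_eval)
        assert np.abs(tg.activities).max() == 0.0
        assert np.abs(tg.xs[:, :conn.n_total] - tp.xs).max() < 1e-7

    def test_single_cell_activity_closed_form(self):
        """Constant supra-threshold drive: the activity relaxes toward
        tau_act * h * (V - theta_b) and the gain switches off when it
        crosses the threshold."""
        conn = ConnectivityMatrices(
            w_ba=np.zeros((1, 1)), w_ab=np.ones((1, 1)),
            w_gb=np.ones((1, 1)), w_ga=np.zeros((1, 1)),
        )
        params = RetinaParams(tau_b=10.0, tau_a=10.0, tau_g=5.0,
                              theta_b=0.2, tau_act=40.0, h_act=0.05)
        v_hold = 1.2

        class Hold:
            ts = None
            def __call__(self, t):
                return np.array([v_hold / 10.0, 0.0, 0.0])

        x0 = np.concatenate([[v_hold], [0.0, 0.0], [0.0]])
        traj = integrate_gain_control(x0, Hold(), (0, 300), params, conn,
                                     t_eval=np.linspace(0, 300, 601))
        a_inf = params.tau_act * params.h_act * (v_hold - params.theta_b)
        a_t = traj.activities[:, 0]
        expected = a_inf * (1 - np.exp(-traj.ts / params.tau_act))
        assert np.abs(a_t - expected).max() < 1e-6
        # gain switches off once the activity passes theta_act
        assert a_inf > params.theta_act
        crossing_events = [e for e in traj.events if e[1] == e[2]] or traj.events
        assert traj.n_events >= 1

    def test_binary_gain_matches_nonlinear_oracle(self, flash_forcing):
        params, conn = self._network()
        forcing = _scaled_forcing(conn, params)
        t_eval = np.linspace(0, 300, 301)
        x0 = np.zeros(conn.n_total + conn.nb)
        traj = integrate_gain_control(x0, forcing, (0, 300), params, conn,
                                     t_eval=t_eval)
        ref = reference_trajectory(x0, forcing, (0, 300), params, conn, t_eval,
                                   gain_control=True, gain="binary",
                                   rtol=1e-10, atol=1e-12, max_step=0.5)
        assert traj.n_events >= 1
        assert np.abs(traj.xs - ref).max() < 1e-5


def _scaled_forcing(conn, params):
    """Flash forcing resized to the 3+2+1 gain-control network."""
    import numpy as np
    from retinet.stimuli import DriveForcing, FullFieldFlash, compute_drive, make_dog_kernel

    kern = make_dog_kernel(0.02, 0.04, center=(0.0, 0.0))
    ts = np.arange(0.0, 300.001, 0.1)
    stim = FullFieldFlash(contrast=1.0, t_on=10, t_off=200, ramp=5)
    d = compute_drive(kern, stim, ts)
    drives = np.array([d * (0.8 + 0.3 * i) for i in range(conn.nb)])
    tau_b, _, _ = params.tau_vectors(conn.nb, conn.na, conn.ng)
    return DriveForcing(ts, drives, tau_b, conn.n_total)


class TestStochastic:
    def test_reproducible_given_seed(self, small_network):
        params, conn = small_network
        noise = WhiteNoiseForcing(None, 0.1, conn.n_total, nb=conn.nb, seed=5)
        a = integrate_pwl(np.zeros(conn.n_total), noise, (0, 50), params, conn,
                         max_step=0.2, seed=5)
        b = integrate_pwl(np.zeros(conn.n_total), noise, (0, 50), params, conn,
                         max_step=0.2, seed=5)
        assert np.array_equal(a.xs, b.xs)
        c = integrate_pwl(np.zeros(conn.n_total), noise, (0, 50), params, conn,
                         max_step=0.2, seed=6)
        assert not np.array_equal(a.xs, c.xs)

    def test_noise_respects_b_only_mask(self, small_network):
        params, conn = small_network
        conn0 = ConnectivityMatrices(
            w_ba=0 * conn.w_ba, w_ab=0 * conn.w_ab,
            w_gb=0 * conn.w_gb, w_ga=0 * conn.w_ga,
        )
        noise = WhiteNoiseForcing(None, 0.3, conn.n_total, nb=conn.nb,
                                  b_only=True, seed=1)
        traj = integrate_pwl(np.zeros(conn.n_total), noise, (0, 100),
                            params, conn0, max_step=0.2)
        assert np.abs(traj.xs[:, conn.nb:]).max() == 0.0
        assert np.abs(traj.xs[:, :conn.nb]).max() > 0.0
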