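"""Unit and property tests for the unified Kalman-filter observer."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import magest as mg
from magest.observer import FREE_PARAMS, _filter_estimates


def dense_kalman_oracle(z, v, q, p0):
    """Textbook matrix Kalman filter, written independently of the package."""
    F = np.array([[0.0, 1.0], [0.0, 1.0]])
    H = np.array([[1.0, 0.0]])
    Q = np.diag([v, q])
    X = np.array([z[0], z[0]])
    P = np.diag([p0, p0])
    xs, ms, k1s, k2s = [], [], [], []
    for zi in z:
        Xp = F @ X
        Pp = F @ P @ F.T + Q
        S = (H @ Pp @ H.T + 1.0).item()
        K = Pp @ H.T / S
        X = Xp + (K * (zi - (H @ Xp).item())).ravel()
        P = (np.eye(2) - K @ H) @ Pp
        xs.append(X[0]); ms.append(X[1]); k1s.append(K[0, 0]); k2s.append(K[1, 0])
    return np.array(xs), np.array(ms), np.array(k1s), np.array(k2s)


class TestTransforms:
    def test_log_transform_anchors(self):
        assert mg.log_transform(0.0, d0=1.0) == 0.0
        assert mg.log_transform(1.0, d0=1.0) == pytest.approx(np.log(2))
        assert mg.log_transform(5.0, d0=5.0) == pytest.approx(np.log(2))

    @pytest.mark.parametrize("d", [400.0, 1150.0, 1900.0])
    def test_roundtrip_is_identity(self, d):
        z = mg.log_transform(d, d0=1.0)
        assert mg.back_transform(z, d0=1.0, delta_x=0.0) == pytest.approx(d, rel=1e-12)

    def test_shift_increases_output(self):
        base = mg.back_transform(7.0, d0=1.0, delta_x=0.0)
        assert mg.back_transform(7.0, d0=1.0, delta_x=0.1) > base

    def test_paper_literal_inverse_agrees_for_large_magnitudes(self):
        # exp(x) vs expm1(x) conventions converge when d >> d0
        z = mg.log_transform(1500.0, d0=1.0)
        exact = mg.back_transform(z, 1.0)
        literal = mg.back_transform(z, 1.0, paper_literal_inverse=True)
        assert literal == pytest.approx(exact, rel=1e-3)

    def test_negative_magnitude_rejected(self):
        with pytest.raises(ValueError):
            mg.log_transform(-1.0, d0=1.0)

    @given(st.floats(0.0, 1e6), st.floats(0.01, 100.0))
    def test_roundtrip_property(self, d, d0):
        z = mg.log_transform(d, d0)
        assert mg.back_transform(z, d0) == pytest.approx(d, rel=1e-9, abs=1e-9)


class TestStaticAndIterative:
    def test_static_limits(self):
        x = np.array([1.0, 2.0, 3.0])
        assert np.allclose(mg.static_estimate(x, 1.0, 9.0), x)
        assert np.allclose(mg.static_estimate(x, 0.0, 9.0), 9.0)

    def test_static_central_tendency_is_one_minus_w(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 50_000)
        y = mg.static_estimate(x, w=0.58, prior_mean=0.0)
        slope = np.polyfit(x, y, 1)[0]
        assert 1 - slope == pytest.approx(0.42, abs=1e-9)

    def test_iterative_limits(self):
        z = np.array([1.0, 5.0, 2.0, 4.0])
        assert np.allclose(mg.iterative_estimate(z, 1.0, 0.0), z)
        assert np.allclose(mg.iterative_estimate(z, 0.0, 3.0), 3.0)

    def test_iterative_geometric_convergence_to_constant_input(self):
        z = np.full(60, 2.0)
        y = mg.iterative_estimate(z, 0.3, y0=0.0)
        gaps = 2.0 - y
        assert np.allclose(gaps[1:] / gaps[:-1], 0.7)

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_gain_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            mg.iterative_estimate([1.0, 2.0], bad, 0.0)
        with pytest.raises(ValueError):
            mg.static_estimate([1.0, 2.0], bad, 0.0)


class TestKalmanFilter:
    def test_matches_dense_matrix_oracle(self):
        rng = np.random.default_rng(3)
        z = rng.normal(7.0, 0.4, 200)
        v, q = 1.3, 0.4
        params = mg.ObserverParams("two_state", v_over_r=v, q_over_r=q)
        x_hat, trace = mg.kalman_filter_two_state(z, params)
        xs, ms, k1s, k2s = dense_kalman_oracle(z, v, q, 10.0 * (v + q + 1.0))
        assert np.allclose(x_hat, xs, atol=1e-9)
        assert np.allclose(trace.m_hat, ms, atol=1e-9)
        assert np.allclose(trace.k1, k1s, atol=1e-12)
        assert np.allclose(trace.k2, k2s, atol=1e-12)

    def test_matches_statsmodels_filter(self):
        KalmanFilter = pytest.importorskip(
            "statsmodels.tsa.statespace.kalman_filter"
        ).KalmanFilter
        v, q = 0.8, 0.15
        rng = np.random.default_rng(5)
        z = rng.normal(7.0, 0.3, 80)
        kf = KalmanFilter(k_endog=1, k_states=2)
        kf["design"] = np.array([[1.0, 0.0]])
        kf["transition"] = np.array([[0.0, 1.0], [0.0, 1.0]])
        kf["selection"] = np.eye(2)
        kf["state_cov"] = np.diag([v, q])
        kf["obs_cov"] = np.array([[1.0]])
        p0 = 10.0 * (v + q + 1.0)
        # statsmodels expects the one-step-ahead prior of the first trial
        kf.initialize_known(np.array([z[0], z[0]]),
                            np.array([[p0 + v, p0], [p0, p0 + q]]))
        kf.bind(z.reshape(1, -1))
        res = kf.filter()
        params = mg.ObserverParams("two_state", v_over_r=v, q_over_r=q)
        x_hat, trace = mg.kalman_filter_two_state(z, params)
        assert np.allclose(res.filtered_state[0], x_hat, atol=1e-9)
        assert np.allclose(res.filtered_state[1], trace.m_hat, atol=1e-9)

    def test_fast_path_equals_full_recursion(self):
        rng = np.random.default_rng(11)
        z = rng.normal(7.0, 0.5, 500)
        for v, q in [(0.0, 0.7), (2.0, 0.0), (1.2, 0.3), (0.01, 5.0)]:
            kind = ("iterative" if v == 0 else "static" if q == 0 else "two_state")
            params = mg.ObserverParams(kind, v_over_r=v, q_over_r=q)
            full, _ = mg.kalman_filter_two_state(z, params)
            fast = _filter_estimates(z, v, q)
            assert np.allclose(full, fast, atol=1e-9)

    def test_iterative_nesting(self):
        """v = 0 reduces the filter to exponential smoothing elementwise."""
        rng = np.random.default_rng(1)
        z = rng.normal(7.0, 0.4, 400)
        params = mg.ObserverParams("iterative", q_over_r=0.5)
        x_hat, _ = mg.kalman_filter_two_state(z, params)
        k, k2 = mg.steady_state_gains(params)
        assert k == pytest.approx(k2, abs=1e-12)
        y = mg.iterative_estimate(z, k, y0=z[0])
        # identical recursions after the gain transient decays
        assert np.allclose(x_hat[50:], y[50:], atol=1e-9)

    def test_static_limit_gains(self):
        """q = 0: the mean gain dies out and k1 -> v/(v+1), the static weight."""
        rng = np.random.default_rng(2)
        z = rng.normal(7.0, 0.4, 5000)
        v = 2.0
        params = mg.ObserverParams("static", v_over_r=v)
        _, trace = mg.kalman_filter_two_state(z, params)
        assert trace.k2[-1] < 1e-3
        assert trace.k1[-1] == pytest.approx(v / (v + 1.0), abs=1e-3)

    def test_measurement_dominates_for_large_v(self):
        rng = np.random.default_rng(4)
        z = rng.normal(7.0, 0.4, 50)
        params = mg.ObserverParams("two_state", v_over_r=1e9, q_over_r=0.0)
        x_hat, _ = mg.kalman_filter_two_state(z, params)
        assert np.allclose(x_hat, z, atol=1e-6)

    def test_nonfinite_measurements_rejected(self):
        params = mg.ObserverParams("two_state", v_over_r=1.0, q_over_r=0.1)
        with pytest.raises(ValueError):
            mg.kalman_filter_two_state([7.0, np.nan, 7.1], params)

    @pytest.mark.parametrize("v", [0.0, 0.1, 1.0, 10.0])
    @pytest.mark.parametrize("q", [0.0, 0.05, 0.5, 3.0])
    def test_gain_bounds_and_psd_covariance(self, v, q):
        rng = np.random.default_rng(8)
        z = rng.normal(7.0, 0.4, 120)
        kind = ("iterative" if v == 0 and q > 0 else
                "static" if q == 0 else "two_state")
        params = mg.ObserverParams(kind, v_over_r=v, q_over_r=q)
        _, trace = mg.kalman_filter_two_state(z, params)
        assert np.all(trace.k2 >= -1e-12)
        assert np.all(trace.k2 <= trace.k1 + 1e-12)
        assert np.all(trace.k1 <= 1.0 + 1e-12)
        eigs = np.linalg.eigvalsh(trace.P)
        assert np.all(eigs >= -1e-9)

    @pytest.mark.parametrize("v", [0.1, 0.5, 1.0])
    @pytest.mark.parametrize("q", [0.1, 0.5, 3.0])
    def test_gains_converge_within_50_trials(self, v, q):
        # with drift (q > 0) the Riccati recursion contracts geometrically;
        # this grid spans the ratios typical of fitted observers
        rng = np.random.default_rng(9)
        z = rng.normal(7.0, 0.4, 60)
        params = mg.ObserverParams("two_state", v_over_r=v, q_over_r=q)
        _, trace = mg.kalman_filter_two_state(z, params)
        assert abs(trace.k1[49] - trace.k1[48]) < 1e-10
        assert abs(trace.k2[49] - trace.k2[48]) < 1e-10

    @pytest.mark.parametrize("v,q", [(10.0, 0.05), (4.0, 0.1), (10.0, 0.1)])
    def test_extreme_ratio_gains_converge_within_200_trials(self, v, q):
        # a large stimulus-variance to drift ratio slows the contraction
        rng = np.random.default_rng(9)
        z = rng.normal(7.0, 0.4, 220)
        params = mg.ObserverParams("two_state", v_over_r=v, q_over_r=q)
        _, trace = mg.kalman_filter_two_state(z, params)
        assert abs(trace.k1[199] - trace.k1[198]) < 1e-10
        assert abs(trace.k2[199] - trace.k2[198]) < 1e-10


class TestSteadyStateGains:
    def test_local_level_golden_ratio(self):
        """v = 0, q = r: the classic local-level gain (sqrt(5)-1)/2."""
        params = mg.ObserverParams("iterative", q_over_r=1.0)
        k1, k2 = mg.steady_state_gains(params)
        golden = (np.sqrt(5.0) - 1.0) / 2.0
        assert k1 == pytest.approx(golden, abs=1e-9)
        assert k2 == pytest.approx(golden, abs=1e-9)

    def test_riccati_fixed_point_is_self_consistent(self):
        # independent check: iterate the covariance recursion from scratch
        from magest.observer import _riccati_step, _initial_p
        for v, q in [(0.5, 0.2), (3.0, 1.0), (0.0, 0.3)]:
            params = mg.ObserverParams("two_state", v_over_r=v, q_over_r=q)
            k1, k2 = mg.steady_state_gains(params)
            p = _initial_p(v, q)
            for _ in range(5000):
                a, b, p = _riccati_step(p, v, q)
            assert k1 == pytest.approx(a, abs=1e-8)
            assert k2 == pytest.approx(b, abs=1e-8)

    def test_degenerate_and_extreme_limits(self):
        assert mg.steady_state_gains(mg.ObserverParams("static", v_over_r=0.0)) == \
            pytest.approx((0.0, 0.0), abs=1e-9)
        _, k2 = mg.steady_state_gains(mg.ObserverParams("iterative", q_over_r=1e9))
        assert k2 > 0.999

    @given(st.floats(0.0, 50.0), st.floats(0.0, 50.0))
    def test_gain_ordering_property(self, v, q):
        params = mg.ObserverParams("two_state", v_over_r=v, q_over_r=q)
        k1, k2 = mg.steady_state_gains(params)
        assert -1e-12 <= k2 <= k1 <= 1.0 + 1e-12


class TestResponseTimecourse:
    def test_veridical_limit(self):
        rng = np.random.default_rng(6)
        d = rng.uniform(400, 1900, 200)
        params = mg.ObserverParams("two_state", v_over_r=1e9, q_over_r=0.0)
        resp = mg.simulate_response_timecourse(d, params)
        assert np.allclose(resp, d, rtol=1e-6)

    def test_order_sensitivity_by_model_kind(self):
        """Reordering stimuli strongly changes iterative/two-state predictions;
        the static observer is far less order-dependent (its residual order
        dependence comes only from the slowly-learned prior mean), and the
        fixed-prior static map is exactly order-invariant as a multiset."""
        walk = mg.gen_random_walk_sequence(2000, 25.0, (400, 1900), seed=13)
        perm = mg.permute_sequence(walk, seed=14)
        gaps = {}
        for kind, v, q in [("static", 1.0, 0.0), ("iterative", 0.0, 0.5),
                           ("two_state", 1.0, 0.3)]:
            params = mg.ObserverParams(kind, v_over_r=v, q_over_r=q)
            c = {}
            for label, seq in [("walk", walk), ("perm", perm)]:
                resp = mg.simulate_response_timecourse(seq.values, params)
                c[label] = 1.0 - np.polyfit(seq.values, resp, 1)[0]
            gaps[kind] = abs(c["walk"] - c["perm"])
        assert gaps["iterative"] > 0.1
        assert gaps["two_state"] > 0.1
        assert gaps["static"] < 0.05
        # Eq.-1-style static map: exact multiset invariance under reordering
        y_walk = mg.static_estimate(walk.values, w=0.6, prior_mean=1150.0)
        y_perm = mg.static_estimate(perm.values, w=0.6, prior_mean=1150.0)
        assert np.allclose(np.sort(y_walk), np.sort(y_perm))

    def test_central_tendency_compresses_output_range(self):
        rng = np.random.default_rng(10)
        d = rng.uniform(400, 1900, 1000)
        params = mg.ObserverParams("two_state", v_over_r=1.0, q_over_r=0.1)
        resp = mg.simulate_response_timecourse(d, params)
        assert resp.std() < d.std()


class TestObserverParams:
    def test_model_constraints_enforced(self):
        with pytest.raises(ValueError):
            mg.ObserverParams("static", v_over_r=1.0, q_over_r=0.5)
        with pytest.raises(ValueError):
            mg.ObserverParams("iterative", v_over_r=0.5)
        with pytest.raises(ValueError):
            mg.ObserverParams("two_state", v_over_r=-1.0)
        with pytest.raises(ValueError):
            mg.ObserverParams("two_state", d0=0.0)

    def test_free_parameter_layout(self):
        assert FREE_PARAMS["static"] == ("v_over_r", "delta_x")
        assert FREE_PARAMS["iterative"] == ("q_over_r", "delta_x")
        assert FREE_PARAMS["two_state"] == ("v_over_r", "q_over_r", "delta_x")
        p = mg.ObserverParams("two_state", v_over_r=1.0, q_over_r=0.2)
        p2 = p.with_free_values([2.0, 0.3, -0.1])
        assert (p2.v_over_r, p2.q_over_r, p2.delta_x) == (2.0, 0.3, -0.1)
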