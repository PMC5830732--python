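import numpy as np
import pytest

from hillgrn.basis import smoothing_fit
from hillgrn.estimator import (
    GPMConfig,
    GPMWorkspace,
    TimeSeriesData,
    inner_objective,
    inner_solve,
    outer_objective,
    outer_solve,
)
from hillgrn.model import LogParameterSet, from_log, to_log

SMALL = GPMConfig(lam=150.0, n_knots=20, quad_points=5)


def _workspace(case, config=SMALL):
    return GPMWorkspace(case["network"], case["data"], config.make_basis(case["data"]), config)


class TestTimeSeriesData:
    def test_rejects_unsorted_times(self):
        with pytest.raises(ValueError, match="increasing"):
            TimeSeriesData([0.0, 0.0, 1.0], np.zeros((3, 1)))

    def test_rejects_negative_values(self):
        with pytest.raises(ValueError, match="non-negative"):
            TimeSeriesData([0.0, 1.0], [[1.0], [-0.5]])

    def test_window_must_cover_times(self):
        with pytest.raises(ValueError, match="window"):
            TimeSeriesData([0.0, 1.0], np.ones((2, 1)), t0=0.5)

    def test_missing_allowed(self):
        data = TimeSeriesData([0.0, 1.0], [[1.0], [np.nan]])
        assert data.n_times == 2


class TestInnerObjective:
    def test_lambda_to_zero_is_plain_least_squares(self, two_gene_case):
        # oracle: with a vanishing penalty the objective is the data SSE
        config = GPMConfig(lam=1e-12, n_knots=20)
        ws = _workspace(two_gene_case, config)
        data = two_gene_case["data"]
        coeffs = smoothing_fit(ws.basis, data.times, data.values, ridge=1e-8)
        theta = to_log(two_gene_case["truth"])
        obj = inner_objective(coeffs, theta, data, two_gene_case["network"],
                              config=config, workspace=ws)
        fit = ws.phi_obs @ coeffs.C.T
        oracle = float(np.sum((data.values - fit) ** 2))
        assert obj == pytest.approx(oracle, rel=1e-6, abs=1e-9)

    def test_penalty_linear_in_lambda(self, two_gene_case):
        data = two_gene_case["data"]
        net = two_gene_case["network"]
        theta = to_log(two_gene_case["truth"])
        cfg1 = GPMConfig(lam=150.0, n_knots=20)
        cfg2 = GPMConfig(lam=300.0, n_knots=20)
        ws1, ws2 = _workspace(two_gene_case, cfg1), _workspace(two_gene_case, cfg2)
        coeffs = smoothing_fit(ws1.basis, data.times, data.values, ridge=1e-8)
        data_term = float(np.sum(ws1.data_residuals(coeffs) ** 2))
        obj1 = inner_objective(coeffs, theta, data, net, config=cfg1, workspace=ws1)
        obj2 = inner_objective(coeffs, theta, data, net, config=cfg2, workspace=ws2)
        assert obj2 - data_term == pytest.approx(2 * (obj1 - data_term), rel=1e-10)

    def test_near_zero_on_true_trajectory(self, two_gene_case):
        # spline representation of the exact trajectory, evaluated with the
        # true parameters, leaves almost nothing in either term
        config = GPMConfig(lam=150.0, n_knots=60)
        ws = _workspace(two_gene_case, config)
        data = two_gene_case["data"]
        from hillgrn.dynamics import simulate

        dense_t = np.linspace(data.t0, data.tf, 600)
        dense = simulate(
            two_gene_case["network"], two_gene_case["truth"],
            two_gene_case["trajectory"].states[0], (data.t0, data.tf), grid=dense_t,
        )
        coeffs = smoothing_fit(ws.basis, dense_t, dense.states, ridge=1e-10)
        theta = to_log(two_gene_case["truth"])
        obj = inner_objective(coeffs, theta, data, two_gene_case["network"],
                              config=config, workspace=ws)
        scale = float(np.sum(data.values**2))
        assert obj < 1e-4 * scale


class TestInnerSolve:
    def test_descent_from_smoothing_init(self, two_gene_case):
        ws = _workspace(two_gene_case)
        data = two_gene_case["data"]
        theta = to_log(two_gene_case["truth"])
        c0 = smoothing_fit(ws.basis, data.times, data.values, ridge=1e-8)
        obj0 = inner_objective(c0, theta, data, two_gene_case["network"],
                               config=SMALL, workspace=ws)
        res = inner_solve(theta, data, two_gene_case["network"],
                          config=SMALL, c_init=c0, workspace=ws)
        assert res.objective <= obj0 + 1e-12

    def test_reconstructs_trajectory_at_truth(self, two_gene_case):
        config = GPMConfig(lam=150.0, n_knots=100)
        ws = _workspace(two_gene_case, config)
        res = inner_solve(to_log(two_gene_case["truth"]), two_gene_case["data"],
                          two_gene_case["network"], config=config, workspace=ws)
        curves = res.coeffs.curves(ws.basis, two_gene_case["data"].times)
        truth_states = two_gene_case["trajectory"].states
        signal = np.ptp(truth_states)
        assert np.max(np.abs(curves - truth_states)) < 0.01 * signal

    def test_large_lambda_tracks_ode(self, two_gene_case):
        # with a dominant penalty the fitted curve obeys the ODE: the
        # per-unit-lambda penalty drops far below the data term scale
        config = GPMConfig(lam=1e6, n_knots=40, inner_max_iter=400)
        ws = _workspace(two_gene_case, config)
        theta = to_log(two_gene_case["truth"])
        res = inner_solve(theta, two_gene_case["data"], two_gene_case["network"],
                          config=config, workspace=ws)
        pen = float(np.sum(ws.penalty_residuals(res.coeffs, theta) ** 2))
        data_term = float(np.sum(ws.data_residuals(res.coeffs) ** 2))
        assert pen / 1e6 < max(data_term, 1e-8)

    def test_penalty_nonincreasing_in_lambda(self, two_gene_case):
        # raising lambda pulls the profiled curve toward ODE fidelity
        theta = to_log(two_gene_case["truth"])
        raw_penalties = []
        for lam in (1.0, 150.0, 1e4):
            config = GPMConfig(lam=lam, n_knots=20)
            ws = _workspace(two_gene_case, config)
            res = inner_solve(theta, two_gene_case["data"], two_gene_case["network"],
                              config=config, workspace=ws)
            # unweighted collocation mismatch (strip lam from the residuals)
            pen = ws.penalty_residuals(res.coeffs, theta) / np.sqrt(lam)
            raw_penalties.append(float(np.sum(pen**2)))
        assert raw_penalties[0] >= raw_penalties[1] >= raw_penalties[2]

    def test_reduces_to_linear_smoothing_without_penalty(self, two_gene_case):
        # full-rank basis, lam ~ 0: the inner solution is the analytic
        # least-squares fit
        config = GPMConfig(lam=1e-12, n_knots=10)
        ws = _workspace(two_gene_case, config)
        data = two_gene_case["data"]
        res = inner_solve(to_log(two_gene_case["truth"]), data,
                          two_gene_case["network"], config=config, workspace=ws)
        A = ws.phi_obs
        for i in range(2):
            oracle = np.linalg.lstsq(A, data.values[:, i], rcond=None)[0]
            np.testing.assert_allclose(res.coeffs.C[i], oracle, atol=1e-5)


class TestOuterObjective:
    def test_nonnegative(self, two_gene_case):
        theta = to_log(two_gene_case["truth"])
        assert outer_objective(theta, two_gene_case["data"],
                               two_gene_case["network"], config=SMALL) >= 0

    def test_small_at_truth(self, two_gene_case):
        config = GPMConfig(lam=150.0, n_knots=60)
        obj = outer_objective(to_log(two_gene_case["truth"]), two_gene_case["data"],
                              two_gene_case["network"], config=config)
        scale = float(np.sum(two_gene_case["data"].values ** 2))
        assert obj < 1e-3 * scale

    def test_perturbing_exponent_increases_misfit(self, two_gene_case):
        config = GPMConfig(lam=150.0, n_knots=60)
        theta = to_log(two_gene_case["truth"])
        at_truth = outer_objective(theta, two_gene_case["data"],
                                   two_gene_case["network"], config=config)
        r = theta.r.copy()
        r[0] += 1.0
        perturbed = LogParameterSet(p=theta.p, q=theta.q, s=theta.s, r=r)
        off_truth = outer_objective(perturbed, two_gene_case["data"],
                                    two_gene_case["network"], config=config)
        assert off_truth > at_truth

    def test_local_minimum_at_truth(self, two_gene_case):
        # finite-difference gradient of the profiled objective w.r.t.
        # theta_p is small at the true parameters (noise-free data)
        config = GPMConfig(lam=150.0, n_knots=60)
        theta = to_log(two_gene_case["truth"])
        vec = theta.to_vector()
        f0 = outer_objective(theta, two_gene_case["data"], two_gene_case["network"],
                             config=config)
        eps = 1e-4
        grad = []
        for j in range(6):  # theta_p block of the 2-gene system
            vp = vec.copy()
            vp[j] += eps
            fp = outer_objective(LogParameterSet.from_vector(vp, 2, 2),
                                 two_gene_case["data"], two_gene_case["network"],
                                 config=config)
            grad.append((fp - f0) / eps)
        scale = float(np.sum(two_gene_case["data"].values ** 2))
        assert np.max(np.abs(grad)) < 1e-3 * scale


class TestOuterSolve:
    def test_empty_mask_returns_init(self, two_gene_case):
        theta = to_log(two_gene_case["truth"])
        mask = np.zeros(8, dtype=bool)
        res = outer_solve(theta, mask, two_gene_case["data"],
                          two_gene_case["network"], config=SMALL)
        np.testing.assert_array_equal(res.theta.to_vector(), theta.to_vector())
        assert res.success

    def test_objective_never_worse_than_init(self, two_gene_case):
        theta = to_log(two_gene_case["truth"])
        vec = theta.to_vector() + 0.3
        init = LogParameterSet.from_vector(vec, 2, 2)
        res = outer_solve(init, init.theta_p_mask(), two_gene_case["data"],
                          two_gene_case["network"], config=SMALL)
        assert res.objective <= res.initial_objective + 1e-12

    def test_result_parameters_positive(self, two_gene_case):
        theta = to_log(two_gene_case["truth"])
        init = LogParameterSet.from_vector(theta.to_vector() - 1.0, 2, 2)
        res = outer_solve(init, init.theta_p_mask(), two_gene_case["data"],
                          two_gene_case["network"], config=SMALL)
        params = from_log(res.theta)
        assert np.all(params.P > 0) and np.all(params.Q > 0)
        assert np.all(params.S > 0) and np.all(params.R > 0)

    def test_recovers_theta_p_from_perturbed_init(self, two_gene_case):
        # exponents at truth, rest perturbed +-20%: the profiled solve
        # pulls P, S, Q back within 5%
        truth = two_gene_case["truth"]
        theta = to_log(truth)
        rng = np.random.default_rng(3)
        pert = rng.uniform(-np.log(1.2), np.log(1.2), size=6)
        init = LogParameterSet(
            p=theta.p + pert[:2], q=theta.q + pert[2:4], s=theta.s + pert[4:], r=theta.r
        )
        config = GPMConfig(lam=150.0, n_knots=100, outer_max_nfev=300)
        res = outer_solve(init, init.theta_p_mask(), two_gene_case["data"],
                          two_gene_case["network"], config=config)
        est = from_log(res.theta)
        for a, b in [(est.P, truth.P), (est.S, truth.S), (est.Q, truth.Q)]:
            np.testing.assert_allclose(a, b, rtol=0.05)

    def test_invalid_mask_shape(self, two_gene_case):
        theta = to_log(two_gene_case["truth"])
        with pytest.raises(ValueError, match="free_mask"):
            outer_solve(theta, np.ones(3, dtype=bool), two_gene_case["data"],
                        two_gene_case["network"], config=SMALL)


class TestConstraintElimination:
    def test_mapped_parameters_positive_for_random_theta(self):
        # 1e5 standard-normal(0, 5^2) draws all map to positive parameters
        rng = np.random.default_rng(99)
        draws = rng.normal(0.0, 5.0, size=100_000)
        assert np.all(np.exp(draws) > 0)
        theta = LogParameterSet(
            p=draws[:25_000], q=draws[25_000:50_000],
            s=draws[50_000:75_000], r=draws[75_000:],
        )
        params = from_log(theta)
        for arr in (params.P, params.S, params.Q, params.R):
            assert np.all(arr > 0)
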