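import numpy as np
import pytest

from mliv import (
    FeatureSpec,
    IVDataset,
    SimulationConfig,
    constrained_stage_two,
    fit_stage_one,
    fit_two_stage,
    gen_valid,
    gen_non_instrument,
    hat_matrix,
    min_constraint_value,
    ols_fit,
    preset_specs,
    traditional_two_stage,
)


def _toy_qcqp(seed, n=40):
    """2-parameter instance for brute-force comparison."""
    rng = np.random.default_rng(seed)
    X_y = rng.standard_normal((n, 2))
    X_r = rng.standard_normal((n, 3))
    y = X_y @ np.array([1.0, -0.5]) + rng.standard_normal(n)
    return y, X_y, hat_matrix(X_r)


def _grid_eval(y, X_y, H, eps_prime, b1, b2):
    B1, B2 = np.meshgrid(b1, b2, indexing="ij")
    betas = np.column_stack([B1.ravel(), B2.ravel()])
    R = y[None, :] - betas @ X_y.T
    obj = np.einsum("ij,ij->i", R, R)
    W = R @ H.Q
    cv = np.einsum("ij,ij->i", W, W)
    feas = cv <= eps_prime
    if not feas.any():
        return None, None
    k = np.flatnonzero(feas)[np.argmin(obj[feas])]
    return obj[k], betas[k]


def _grid_min(y, X_y, H, eps_prime, lim=3.0, step=0.01):
    """Grid search over beta in [-lim, lim]^2 with local refinement
    (independent oracle; a boundary optimum has first-order grid error,
    so the grid is re-meshed around the incumbent twice)."""
    b = np.arange(-lim, lim + step / 2, step)
    best, center = _grid_eval(y, X_y, H, eps_prime, b, b)
    if best is None:
        return None
    for fine in (step / 10, step / 100, step / 1000, step / 10000):
        w = fine * 150
        b1 = np.arange(center[0] - w, center[0] + w, fine)
        b2 = np.arange(center[1] - w, center[1] + w, fine)
        cand, c2 = _grid_eval(y, X_y, H, eps_prime, b1, b2)
        if cand is not None and cand < best:
            best, center = cand, c2
    return best


class TestStageOne:
    def test_recovers_dgp_coefficients(self):
        data = gen_valid(SimulationConfig(n=10_000, seed=6))
        fit = fit_stage_one(data, FeatureSpec(["x1", "z1", "z1^2"],
                                              include_intercept=True))
        # t = x + z + z^2 + e1: intercept ~ 0, slopes ~ 1
        np.testing.assert_allclose(fit.omega[1:], [1, 1, 1], atol=0.05)
        assert abs(fit.omega[0]) < 0.05
        assert fit.relevance.passed

    def test_null_target_gives_null_fit(self, rng):
        X = rng.standard_normal((50, 1))
        Z = rng.standard_normal((50, 1))
        d = IVDataset(X=X, Z=Z, t=np.zeros(50), y=np.zeros(50))
        fit = fit_stage_one(d, FeatureSpec(["x1", "z1"]))
        np.testing.assert_allclose(fit.omega, 0, atol=1e-12)
        np.testing.assert_allclose(fit.t_hat, 0, atol=1e-12)

    def test_matches_shared_ols(self, valid_data):
        spec = FeatureSpec(["x1", "z1"])
        fit = fit_stage_one(valid_data, spec)
        ref = ols_fit(np.column_stack([valid_data.X[:, 0], valid_data.Z[:, 0]]),
                      valid_data.t)
        np.testing.assert_allclose(fit.omega, ref.coefficients, atol=1e-12)


class TestMinConstraintValue:
    def test_full_projector_reduces_to_ols(self, rng):
        X_y = rng.standard_normal((10, 2))
        y = rng.standard_normal(10)
        H = hat_matrix(rng.standard_normal((10, 10)))  # H = I
        beta, val = min_constraint_value(X_y, H, y)
        ref = ols_fit(X_y, y)
        np.testing.assert_allclose(beta, ref.coefficients, atol=1e-8)
        assert val == pytest.approx(ref.sse, abs=1e-8)

    def test_lm_lm_coincides_with_objective_minimizer(self):
        """When the stage-two design lies inside the remainder-model
        span, the constraint minimizer IS the OLS minimizer."""
        data = gen_valid(SimulationConfig(n=300, seed=8))
        spec_one = FeatureSpec(["x1", "z1"])
        s1 = fit_stage_one(data, spec_one, check_relevance=False)
        X_y = np.column_stack([data.X[:, 0], s1.t_hat])
        X_r = np.column_stack([data.X[:, 0], data.Z[:, 0]])
        beta_c, _ = min_constraint_value(X_y, hat_matrix(X_r), data.y)
        beta_o = ols_fit(X_y, data.y).coefficients
        np.testing.assert_allclose(beta_c, beta_o, atol=1e-6)

    @pytest.mark.parametrize("seed", [0, 3, 9])
    def test_agrees_with_grid_search(self, seed):
        y, X_y, H = _toy_qcqp(seed)
        beta, val = min_constraint_value(X_y, H, y)
        b = np.arange(-3, 3.001, 0.01)
        B1, B2 = np.meshgrid(b, b, indexing="ij")
        betas = np.column_stack([B1.ravel(), B2.ravel()])
        W = (y[None, :] - betas @ X_y.T) @ H.Q
        grid_val = np.einsum("ij,ij->i", W, W).min()
        assert val <= grid_val + 1e-10
        assert abs(val - grid_val) < 1e-2


class TestConstrainedStageTwo:
    def test_infinite_tolerance_is_traditional_ols(self, rng):
        y, X_y, H = _toy_qcqp(1)
        res = constrained_stage_two(y, X_y, H, float("inf"))
        assert res.status == "inactive"
        np.testing.assert_allclose(res.beta, ols_fit(X_y, y).coefficients,
                                   atol=1e-8)

    @pytest.mark.parametrize("seed", range(6))
    def test_objective_matches_grid_oracle_when_active(self, seed):
        y, X_y, H = _toy_qcqp(seed)
        _, vmin = min_constraint_value(X_y, H, y)
        cv_ols = H.quad(y - X_y @ ols_fit(X_y, y).coefficients)
        eps = vmin + 0.25 * (cv_ols - vmin)  # forces the active case
        res = constrained_stage_two(y, X_y, H, eps)
        assert res.status == "active"
        oracle = _grid_min(y, X_y, H, eps)
        assert res.objective_value <= oracle + 1e-6
        assert abs(res.objective_value - oracle) < 1e-3

    def test_infeasible_when_tolerance_below_minimum(self):
        y, X_y, H = _toy_qcqp(2)
        _, vmin = min_constraint_value(X_y, H, y)
        res = constrained_stage_two(y, X_y, H, 0.5 * vmin)
        assert res.status == "infeasible"
        assert res.beta is None
        assert res.constraint_value == pytest.approx(vmin, rel=1e-10)

    def test_objective_nonincreasing_in_epsilon_prime(self):
        y, X_y, H = _toy_qcqp(4)
        _, vmin = min_constraint_value(X_y, H, y)
        sse_ols = ols_fit(X_y, y).sse
        last = np.inf
        for f in (1.05, 1.5, 3.0, 10.0, np.inf):
            res = constrained_stage_two(y, X_y, H, vmin * f)
            assert res.status in ("active", "inactive")
            assert res.objective_value <= last + 1e-9
            last = res.objective_value
        assert last == pytest.approx(sse_ols, abs=1e-8)

    def test_active_solution_sits_on_boundary(self):
        y, X_y, H = _toy_qcqp(5)
        _, vmin = min_constraint_value(X_y, H, y)
        eps = vmin * 1.5
        res = constrained_stage_two(y, X_y, H, eps)
        assert res.status == "active"
        assert res.constraint_value == pytest.approx(eps, rel=1e-6)

    def test_negative_tolerance_rejected(self):
        y, X_y, H = _toy_qcqp(0)
        with pytest.raises(ValueError):
            constrained_stage_two(y, X_y, H, -1.0)

    def test_epsilon_zero_with_unreachable_zero_is_infeasible(self):
        y, X_y, H = _toy_qcqp(6)
        _, vmin = min_constraint_value(X_y, H, y)
        assert vmin > 0
        res = constrained_stage_two(y, X_y, H, 0.0)
        assert res.status == "infeasible"


class TestTraditionalTwoStage:
    def test_linear_case_matches_classical_iv_ratio(self):
        """With one covariate and one instrument, 2SLS equals the
        classical ratio z'M_x y / z'M_x t (x partialled out)."""
        rng = np.random.default_rng(11)
        n = 2000
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        e1 = rng.standard_normal(n)
        e2 = 0.8 * e1 + 0.6 * rng.standard_normal(n)
        t = x + z + e1
        y = x + 2.0 * t + e2
        d = IVDataset(X=x[:, None], Z=z[:, None], t=t, y=y)
        _, beta, _, _ = traditional_two_stage(
            d, FeatureSpec(["x1", "z1"]), FeatureSpec(["x1", "t_hat"]))
        Mx = np.eye(n) - np.outer(x, x) / (x @ x)
        iv_ratio = (z @ Mx @ y) / (z @ Mx @ t)
        assert beta[1] == pytest.approx(iv_ratio, abs=1e-8)

    def test_exogenous_case_agrees_with_ols(self):
        rng = np.random.default_rng(13)
        n = 5000
        x, z = rng.standard_normal((2, n))
        t = x + z + rng.standard_normal(n)
        y = x + t + rng.standard_normal(n)  # e1 independent of e2
        d = IVDataset(X=x[:, None], Z=z[:, None], t=t, y=y)
        _, beta, _, _ = traditional_two_stage(
            d, FeatureSpec(["x1", "z1"]), FeatureSpec(["x1", "t_hat"]))
        beta_ols = ols_fit(np.column_stack([x, t]), y).coefficients
        np.testing.assert_allclose(beta[1], beta_ols[1], atol=0.1)

    def test_recovers_unit_effect_on_robustness_dgp(self):
        from mliv import gen_robustness
        est = []
        for seed in range(60):
            d = gen_robustness(SimulationConfig(
                dgp="robustness", n=1000, pi=1.0, f_name="quadratic", seed=seed))
            _, beta, _, _ = traditional_two_stage(
                d, FeatureSpec(["x1", "z1", "z1^2"], include_intercept=True),
                FeatureSpec(["x1", "t_hat"]))
            est.append(beta[1])
        assert abs(np.median(est) - 1.0) < 0.1


class TestFitTwoStage:
    SPECS = preset_specs("identification")

    def _fit(self, data, gamma=0.01):
        return fit_two_stage(data, self.SPECS["stage_one"],
                             self.SPECS["stage_two"], self.SPECS["remainder"],
                             gamma=gamma)

    def test_valid_instrument_is_feasible(self):
        fit = self._fit(gen_valid(SimulationConfig(n=1000, seed=21)))
        assert fit.stage_two.status != "infeasible"
        assert fit.validity.passed

    def test_non_instrument_is_flagged(self):
        d = gen_non_instrument(SimulationConfig(
            dgp="non_instrument", n=1000, phi=1.0, seed=21))
        fit = self._fit(d)
        assert fit.stage_two.status == "infeasible"
        assert fit.stage_two.beta is None

    def test_gamma_one_always_feasible(self):
        d = gen_non_instrument(SimulationConfig(
            dgp="non_instrument", n=1000, phi=1.0, seed=22))
        fit = self._fit(d, gamma=1.0)
        assert fit.stage_two.status != "infeasible"

    def test_epsilon_prime_calibrated_from_traditional_remainder(self):
        d = gen_valid(SimulationConfig(n=500, seed=23))
        fit = self._fit(d, gamma=0.02)
        assert fit.stage_two.epsilon_prime == pytest.approx(
            0.02 * fit.r_tilde @ fit.r_tilde)
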