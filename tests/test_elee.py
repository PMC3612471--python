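import numpy as np
import pytest
from scipy import stats

from bjel import (
    CensoredRegressionData,
    adjustment_factor,
    bj_point_estimate,
    el_solve,
    elee_confidence_interval,
    elee_region_grid,
    elee_test,
    sigma2_hat,
)
from bjel.elee import _elee_statistic

from .conftest import make_model_data
from .oracles import naive_sigma2


def _ols_slope(data):
    Xc = data.X - data.X.mean(axis=0)
    return np.linalg.solve(Xc.T @ Xc, Xc.T @ data.Z)


class TestSigma2:
    def test_matches_term_by_term_oracle_on_toy(self, toy4):
        got = sigma2_hat(toy4, [1.0])
        expected = naive_sigma2(toy4.X, toy4.Z, toy4.delta, [1.0])
        np.testing.assert_allclose(got, expected, atol=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_oracle_on_random_samples(self, seed):
        data, _ = make_model_data("A", n=30, cr=0.4, seed=seed)
        got = sigma2_hat(data, [0.9])
        expected = naive_sigma2(data.X, data.Z, data.delta, [0.9])
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_two_covariates_against_oracle(self, rng):
        n = 25
        X = rng.normal(size=(n, 2))
        Z = X @ [1.0, -0.5] + rng.normal(size=n)
        delta = (rng.random(n) > 0.3).astype(int)
        delta[0] = 1
        d = CensoredRegressionData(X=X, Z=Z, delta=delta)
        beta = [1.0, -0.5]
        np.testing.assert_allclose(
            sigma2_hat(d, beta), naive_sigma2(X, Z, delta, beta), atol=1e-10
        )


class TestAdjustmentFactor:
    def test_scalar_reduction(self, toy4):
        comp = adjustment_factor(toy4, [1.0])
        assert comp.cn == pytest.approx(
            float(comp.Sigma1[0, 0] / comp.Sigma2[0, 0])
        )
        assert comp.cn > 0

    def test_invariant_to_covariate_rescaling(self, model_a_small):
        data, _ = model_a_small
        scaled = CensoredRegressionData(
            X=10.0 * data.X, Z=data.Z, delta=data.delta
        )
        c1 = adjustment_factor(data, [0.9]).cn
        c2 = adjustment_factor(scaled, [0.09]).cn
        assert c2 == pytest.approx(c1, rel=1e-10)

    def test_components_are_psd(self, model_a_small):
        data, _ = model_a_small
        comp = adjustment_factor(data, [1.0])
        for M in (comp.Sn, comp.Sigma1, comp.Sigma2):
            assert np.all(np.linalg.eigvalsh(M) >= -1e-12)
        assert np.linalg.matrix_rank(comp.Sn) <= 1


class TestEleeTest:
    def test_uncensored_at_ols_is_null(self, rng):
        d = CensoredRegressionData(
            X=rng.normal(size=25), Z=rng.normal(size=25), delta=np.ones(25)
        )
        res = elee_test(d, _ols_slope(d))
        assert res.ln == pytest.approx(0.0, abs=1e-10)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0, abs=1e-8)

    def test_uncensored_log_ratio_equals_owen_ls_el(self, rng):
        d = CensoredRegressionData(
            X=rng.normal(size=30), Z=rng.normal(size=30), delta=np.ones(30)
        )
        beta = [0.2]
        res = elee_test(d, beta)
        scores = (d.X - d.X.mean(0)) * (d.Z - d.X @ np.array(beta))[:, None]
        assert res.ln == pytest.approx(el_solve(scores).log_ratio, abs=1e-12)

    def test_hull_failure_is_rejection(self):
        # every score row (X_i - Xbar)(Z_i - X_i beta0) is strictly positive
        data = CensoredRegressionData(
            X=[1.0, 2.0, 4.0], Z=[-1.0, -1.0, 1.0], delta=[1, 1, 1]
        )
        res = elee_test(data, [0.0])
        assert res.status == "hull_failure"
        assert res.statistic == np.inf
        assert res.p_value == 0.0

    def test_statistic_invariant_under_reparameterization(self, rng):
        n = 60
        X = rng.normal(size=(n, 2))
        Z = X @ [1.0, 0.5] + rng.normal(size=n)
        C = rng.normal(2.0, 2.0, size=n)
        d = CensoredRegressionData(
            X=X, Z=np.minimum(Z, C), delta=(Z <= C).astype(int)
        )
        A = np.array([[1.5, -0.4], [0.2, 0.8]])
        beta0 = np.array([0.9, 0.6])
        r1 = elee_test(d, beta0)
        d2 = CensoredRegressionData(X=X @ A, Z=d.Z, delta=d.delta)
        r2 = elee_test(d2, np.linalg.solve(A, beta0))
        assert r2.statistic == pytest.approx(r1.statistic, abs=1e-8)


class TestConfidenceInterval:
    def test_endpoint_statistics_hit_critical_value(self):
        data, _ = make_model_data("A", n=120, cr=0.3, seed=9)
        ci = elee_confidence_interval(data, level=0.95)
        crit = stats.chi2.ppf(0.95, 1)
        for endpoint in (ci.lower, ci.upper):
            stat = _elee_statistic(data, [endpoint]).statistic
            assert stat == pytest.approx(crit, abs=0.05)
        assert ci.lower < ci.upper
        assert not ci.unbounded and not ci.degenerate

    def test_levels_nest(self):
        data, _ = make_model_data("A", n=120, cr=0.3, seed=10)
        ci90 = elee_confidence_interval(data, level=0.90)
        ci95 = elee_confidence_interval(data, level=0.95)
        assert ci95.lower <= ci90.lower <= ci90.upper <= ci95.upper

    def test_requires_single_covariate(self, rng):
        X = rng.normal(size=(20, 2))
        d = CensoredRegressionData(
            X=X, Z=rng.normal(size=20), delta=np.ones(20)
        )
        with pytest.raises(ValueError, match="p = 1"):
            elee_confidence_interval(d)


class TestRegionGrid:
    def test_center_is_member_and_far_points_are_not(self):
        data, _ = make_model_data("A", n=120, cr=0.3, seed=12)
        bhat = bj_point_estimate(data).beta
        grid = np.array([[bhat[0]], [bhat[0] + 50.0], [bhat[0] - 50.0]])
        flags = elee_region_grid(data, grid, level=0.95)
        assert flags[0]
        assert not flags[1] and not flags[2]

    def test_empty_grid_rejected(self, toy4):
        with pytest.raises(ValueError, match="empty"):
            elee_region_grid(toy4, np.empty((0, 1)))
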