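import numpy as np
import pytest
from scipy import stats as sps

from bsemfit.fit_indices import (
    DiscrepancySeries,
    FitIndexResult,
    attach_null,
    bcfi,
    brmsea_devm,
    brmsea_ppmc,
    btli,
    chi_square_discrepancy,
    decide,
    discrepancy_series,
    effective_params,
    fit_null_model,
    ppp,
)
from bsemfit.synthetic_data import Dataset, generate


def _series(d_obs, d_rep=None, p_star=10, pD=4.0, N=100, d_obs_null=None, pD_null=None):
    return DiscrepancySeries(
        d_obs=np.asarray(d_obs, dtype=float),
        d_rep=None if d_rep is None else np.asarray(d_rep, dtype=float),
        p_star=p_star, pD=pD, N=N, q=4,
        d_obs_null=None if d_obs_null is None else np.asarray(d_obs_null, dtype=float),
        pD_null=pD_null,
    )


class TestChiSquareDiscrepancy:
    def test_saturated_point_is_zero(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 3))
        S = np.cov(X, rowvar=False, ddof=0)
        xbar = X.mean(axis=0)
        assert chi_square_discrepancy(xbar, S, xbar, S, 40) == pytest.approx(0.0, abs=1e-10)

    def test_hand_computed_toy(self):
        # S = I2, xbar = 0, Sigma = diag(2,2), mu = 0, N = 100
        d = chi_square_discrepancy(np.zeros(2), np.eye(2), np.zeros(2),
                                   2 * np.eye(2), 100)
        assert d == pytest.approx(100 * (2 * np.log(2) + 1 - 2))

    def test_nonnegative_for_random_parameters(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            p = rng.integers(2, 5)
            A = rng.standard_normal((p, p))
            S = A @ A.T + p * np.eye(p)
            B = rng.standard_normal((p, p))
            sigma = B @ B.T + p * np.eye(p)
            mu = rng.standard_normal(p)
            assert chi_square_discrepancy(np.zeros(p), S, mu, sigma, 50) >= 0

    def test_matches_loglikelihood_ratio_oracle(self):
        """D equals -2 (loglik at theta - loglik saturated), computed
        observation-wise with an independent density oracle."""
        rng = np.random.default_rng(7)
        for trial in range(5):
            n, p = 30, rng.integers(2, 5)
            X = rng.standard_normal((n, p)) @ rng.standard_normal((p, p)) + rng.standard_normal(p)
            S = np.cov(X, rowvar=False, ddof=0)
            xbar = X.mean(axis=0)
            B = rng.standard_normal((p, p))
            sigma = B @ B.T + p * np.eye(p)
            mu = rng.standard_normal(p)
            d = chi_square_discrepancy(xbar, S, mu, sigma, n)
            ll_model = sps.multivariate_normal(mu, sigma).logpdf(X).sum()
            ll_sat = sps.multivariate_normal(xbar, S, allow_singular=True).logpdf(X).sum()
            assert d == pytest.approx(-2 * (ll_model - ll_sat), abs=1e-8)


class TestPpp:
    def test_all_below_gives_one(self):
        assert ppp(_series([1, 2, 3], [4, 5, 6])) == 1.0

    def test_half_below_gives_half(self):
        assert ppp(_series([1, 5], [3, 3])) == 0.5

    def test_requires_replicated_series(self):
        with pytest.raises(ValueError):
            ppp(_series([1.0]))


class TestBrmsea:
    def test_floor_at_zero(self):
        s = _series([10.0], [10.0], p_star=10, pD=4)
        assert brmsea_ppmc(s).posterior_mean == 0.0

    def test_ppmc_algebraic_point(self):
        # d_obs - d_rep = 2(p* - pD)  ->  draw value 1/sqrt(N)
        s = _series([12.0], [0.0], p_star=10, pD=4, N=400)
        assert brmsea_ppmc(s).posterior_mean == pytest.approx(1 / 20)

    def test_devm_zero_at_p_star(self):
        s = _series([10.0], p_star=10, pD=4)
        assert brmsea_devm(s).posterior_mean == 0.0

    def test_devm_algebraic_point(self):
        # d_obs = p* + (p* - pD) N  ->  draw value 1
        s = _series([10 + 6 * 100.0], p_star=10, pD=4, N=100)
        assert brmsea_devm(s).posterior_mean == pytest.approx(1.0)

    def test_forms_agree_when_d_rep_equals_pd(self):
        rng = np.random.default_rng(3)
        d_obs = rng.uniform(5, 40, size=50)
        s = _series(d_obs, np.full(50, 4.0), p_star=10, pD=4, N=200)
        np.testing.assert_allclose(brmsea_ppmc(s).draw_series,
                                   brmsea_devm(s).draw_series)

    def test_pathological_pd_rejected(self):
        s = _series([5.0], p_star=10, pD=11)
        with pytest.raises(ValueError, match="p\\*"):
            brmsea_devm(s)


class TestIncrementalIndices:
    def test_bcfi_perfect_fit(self):
        s = _series([10.0], d_obs_null=[100.0], pD_null=3.0)
        assert bcfi(s).posterior_mean == pytest.approx(1.0)

    def test_bcfi_no_improvement_over_null(self):
        s = _series([100.0], d_obs_null=[100.0], pD_null=3.0)
        assert bcfi(s).posterior_mean == pytest.approx(0.0)

    def test_bcfi_clamped_to_unit_interval(self):
        s = _series([5.0, 200.0], d_obs_null=[100.0, 100.0], pD_null=3.0)
        vals = bcfi(s).draw_series
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_btli_perfect_fit(self):
        # R_H = 1 when d_obs - pD = p* - pD, i.e. d_obs = p*
        s = _series([10.0], pD=4, d_obs_null=[100.0], pD_null=3.0)
        assert btli(s).posterior_mean == pytest.approx(1.0)

    def test_btli_zero_when_ratios_match(self):
        # R_H = R_o
        s = _series([4 + 6 * (97 / 7)], pD=4.0, d_obs_null=[100.0], pD_null=3.0)
        assert btli(s).posterior_mean == pytest.approx(0.0, abs=1e-12)


class TestDecide:
    def test_bcfi_interval_classes(self):
        res = FitIndexResult("BCFI", None, 0.975, 0.01, (0.96, 0.99))
        assert decide(res) == (False, "good")
        res = FitIndexResult("BCFI", None, 0.90, 0.01, (0.85, 0.94))
        assert decide(res) == (True, "poor")
        res = FitIndexResult("BCFI", None, 0.95, 0.01, (0.93, 0.97))
        assert decide(res) == (False, "inconclusive")

    def test_brmsea_interval_classes(self):
        res = FitIndexResult("BRMSEA_devm", None, 0.04, 0.01, (0.02, 0.08))
        assert decide(res) == (False, "inconclusive")
        res = FitIndexResult("BRMSEA_devm", None, 0.03, 0.01, (0.01, 0.05))
        assert decide(res) == (False, "good")
        res = FitIndexResult("BRMSEA_devm", None, 0.10, 0.01, (0.07, 0.13))
        assert decide(res) == (True, "poor")

    def test_ppp_bounds(self):
        res = FitIndexResult("PPp", None, 0.5, 0.0, (0.5, 0.5), ppp=0.5)
        assert decide(res) == (False, None)
        res = FitIndexResult("PPp", None, 0.01, 0.0, (0.01, 0.01), ppp=0.01)
        assert decide(res)[0] is True

    def test_unknown_index(self):
        res = FitIndexResult("GFI", None, 0.5, 0.0, (0.4, 0.6))
        with pytest.raises(ValueError, match="unknown index"):
            decide(res)


class TestSeriesFromPosterior:
    def test_seeded_determinism(self, a1_fit):
        s1 = discrepancy_series(a1_fit["data"], a1_fit["draws"],
                                np.random.default_rng(5))
        s2 = discrepancy_series(a1_fit["data"], a1_fit["draws"],
                                np.random.default_rng(5))
        np.testing.assert_array_equal(s1.d_obs, s2.d_obs)
        np.testing.assert_array_equal(s1.d_rep, s2.d_rep)

    def test_replicated_discrepancies_positive(self, a1_fit):
        s = discrepancy_series(a1_fit["data"], a1_fit["draws"],
                               np.random.default_rng(5))
        assert s.d_rep.mean() > 0
        assert np.all(s.d_obs >= 0)
        assert s.p_star == 120
        assert s.q == 33

    def test_ppp_reasonable_for_correct_model(self, a1_fit):
        s = discrepancy_series(a1_fit["data"], a1_fit["draws"],
                               np.random.default_rng(5))
        assert 0.05 < ppp(s) < 0.95

    def test_effective_params_alias(self, a1_fit):
        s = discrepancy_series(a1_fit["data"], a1_fit["draws"],
                               np.random.default_rng(5))
        assert effective_params(s) == s.pD


class TestNullModel:
    def test_null_pd_close_to_item_count(self, model_a85):
        data = generate(model_a85, 2000, seed=21)
        d_obs, _, pd_null = fit_null_model(data, 4000, np.random.default_rng(2))
        # free variances of the diagonal model dominate the deviance
        assert pd_null == pytest.approx(data.p, rel=0.15)

    def test_seeded_determinism(self, model_a85):
        data = generate(model_a85, 100, seed=3)
        a = fit_null_model(data, 50, np.random.default_rng(9))
        b = fit_null_model(data, 50, np.random.default_rng(9))
        np.testing.assert_array_equal(a[0], b[0])

    def test_bcfi_of_independence_data_is_high(self):
        """When the data really are independent, the hypothesized
        diagonal structure matches the null and BCFI sits near 1 for a
        well-fitting (here: the true, diagonal) model."""
        rng = np.random.default_rng(12)
        X = rng.standard_normal((400, 6))
        data = Dataset(X, n=400)
        d_obs, _, pd_null = fit_null_model(data, 500, np.random.default_rng(1))
        s = _series(d_obs, p_star=21, pD=pd_null, N=400,
                    d_obs_null=d_obs, pD_null=pd_null)
        assert bcfi(s).posterior_mean == pytest.approx(0.0)  # same model on both sides
        # and the null deviance stays near p* for truly diagonal data
        assert abs(d_obs.mean() - 21) < 15

    def test_attach_null_length_check(self, model_a85):
        data = generate(model_a85, 100, seed=3)
        d_obs, d_rep, pd_null = fit_null_model(data, 50, np.random.default_rng(9))
        s = _series(np.ones(10))
        with pytest.raises(ValueError, match="length"):
            attach_null(s, d_obs, d_rep, pd_null)
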