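"""Displaced-Gaussian analytics: AUC, OR(z), BOR, absolute risk, normality."""

import numpy as np
import pytest
from scipy import integrate, stats

from polyrisk import (
    GaussianRiskModel,
    absolute_risk,
    auc_gaussian,
    auc_mann_whitney,
    binned_odds_ratio,
    chi2_normality,
    fit_gaussian_summary,
    odds_ratio_tail,
    or_by_percentile,
    population_score_density,
)
from polyrisk.gaussian import GaussianSummary


def _summary(mu1=1.0, mu0=0.0, s1=1.0, s0=1.0, n1=100, n0=100):
    return GaussianSummary(mu_case=mu1, mu_control=mu0, sigma_case=s1,
                           sigma_control=s0, n_case=n1, n_control=n0)


class TestFitGaussianSummary:
    def test_degenerate_stratum_raises(self):
        with pytest.raises(ValueError):
            fit_gaussian_summary(np.array([1.0, 1.0, 0.0, 0.0]),
                                 np.array([1, 1, 0, 0]))

    def test_recovers_generating_moments(self, rng):
        n = 100_000
        scores = np.r_[rng.normal(0.5, 1.0, n), rng.normal(0.0, 1.0, n)]
        labels = np.r_[np.ones(n, int), np.zeros(n, int)]
        s = fit_gaussian_summary(scores, labels)
        se_mu = 1.0 / np.sqrt(n)
        assert abs(s.mu_case - 0.5) < 3 * se_mu
        assert abs(s.mu_control - 0.0) < 3 * se_mu
        assert s.n_case == n and s.n_control == n

    def test_scale_equivariance(self, rng):
        scores = rng.standard_normal(200)
        labels = rng.integers(0, 2, 200)
        a = fit_gaussian_summary(scores, labels)
        b = fit_gaussian_summary(3.0 * scores, labels)
        assert b.mu_case == pytest.approx(3 * a.mu_case)
        assert b.sigma_control == pytest.approx(3 * a.sigma_control)


class TestAnalyticAuc:
    def test_equal_means_give_half(self):
        assert auc_gaussian(_summary(mu1=0.3, mu0=0.3, s1=0.5, s0=2.0)) == 0.5

    def test_agrees_with_mann_whitney_on_large_samples(self, rng):
        n = 50_000
        s = _summary(mu1=0.4, mu0=0.0, s1=1.1, s0=0.9)
        scores = np.r_[rng.normal(s.mu_case, s.sigma_case, n),
                       rng.normal(s.mu_control, s.sigma_control, n)]
        labels = np.r_[np.ones(n, int), np.zeros(n, int)]
        emp = auc_mann_whitney(scores, labels)
        # MC standard error of the empirical AUC is below ~1/sqrt(n)
        assert abs(auc_gaussian(s) - emp) < 3 / np.sqrt(n)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            _summary(s1=0.0)


class TestOddsRatioTail:
    def test_identical_distributions_give_unity(self):
        s = _summary(mu1=0.0, s1=1.0)
        z = np.linspace(-3, 3, 13)
        np.testing.assert_allclose(odds_ratio_tail(s, z), 1.0)

    def test_monte_carlo_tail_count_oracle(self, rng):
        s = _summary()  # N(1,1) vs N(0,1)
        n = 10_000_000
        cases = rng.standard_normal(n) + 1.0
        controls = rng.standard_normal(n)
        z = 1.645
        mc = (cases >= z).mean() / (controls >= z).mean()
        assert odds_ratio_tail(s, z) == pytest.approx(mc, rel=0.02)
        assert odds_ratio_tail(s, z) == pytest.approx(5.19, abs=0.01)

    def test_monotone_in_z_for_equal_variances(self):
        s = _summary()
        z = np.linspace(-4, 6, 101)
        assert np.all(np.diff(odds_ratio_tail(s, z)) >= 0)

    def test_stable_deep_in_the_tail(self):
        s = _summary()
        val = odds_ratio_tail(s, 12.0)
        assert np.isfinite(val) and val > 1e4

    def test_agrees_with_empirical_percentile_curve(self, rng):
        # the analytic red line through the empirical OR points
        n1, n0 = 10_000, 40_000
        s = _summary(n1=n1, n0=n0)
        scores = np.r_[rng.normal(1.0, 1.0, n1), rng.normal(0.0, 1.0, n0)]
        labels = np.r_[np.ones(n1, int), np.zeros(n0, int)]
        curve = or_by_percentile(scores, labels, percentiles=range(0, 99, 7))
        analytic = odds_ratio_tail(s, curve.thresholds)
        ok = ~curve.undefined
        assert np.all((curve.ci_low[ok] <= analytic[ok])
                      & (analytic[ok] <= curve.ci_high[ok]))


class TestDensityAndBor:
    def test_mixture_collapses_when_strata_match(self):
        s = _summary(mu1=0.2, mu0=0.2, s1=0.7, s0=0.7)
        z = np.linspace(-2, 2, 9)
        np.testing.assert_allclose(population_score_density(s, z),
                                   stats.norm.pdf(z, 0.2, 0.7))

    def test_density_integrates_to_one(self):
        s = _summary(mu1=1.5, mu0=-0.5, s1=0.8, s0=1.3, n1=300, n0=900)
        total, _ = integrate.quad(lambda z: population_score_density(s, z), -14, 14)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_bor_unity_for_identical_distributions(self):
        s = _summary(mu1=0.0)
        np.testing.assert_allclose(binned_odds_ratio(s, np.linspace(-3, 3, 7)), 1.0)

    def test_log_bor_linear_with_closed_form_slope(self):
        s = _summary(mu1=0.8, mu0=0.1, s1=0.6, s0=0.6)
        z = np.linspace(-2, 2, 50)
        log_bor = np.log(binned_odds_ratio(s, z))
        slope = np.polyfit(z, log_bor, 1)[0]
        assert slope == pytest.approx((0.8 - 0.1) / 0.6**2, rel=1e-8)

    def test_bor_independent_of_subpopulation_ratio(self, rng):
        # two subpopulations sharing score distributions but different
        # case/control ratios estimate the same BOR
        z_grid = np.array([-0.5, 0.0, 0.5, 1.0])
        bors = []
        for n1, n0 in ((5_000, 45_000), (20_000, 30_000)):
            cases = rng.normal(0.8, 1.0, n1)
            controls = rng.normal(0.0, 1.0, n0)
            bin_w = 0.3
            bor = []
            for z in z_grid:
                c1 = ((cases >= z - bin_w) & (cases < z + bin_w)).mean()
                c0 = ((controls >= z - bin_w) & (controls < z + bin_w)).mean()
                bor.append(c1 / c0)
            bors.append(bor)
        np.testing.assert_allclose(bors[0], bors[1], rtol=0.15)


class TestAbsoluteRisk:
    def test_even_odds(self):
        assert absolute_risk(1.0, 1.0) == pytest.approx(0.5)

    def test_limit_to_certainty(self):
        assert absolute_risk(1e12, 1.0) == pytest.approx(1.0, abs=1e-9)

    def test_monotone_in_bor_and_ratio(self):
        bors = np.geomspace(0.1, 100, 40)
        risks = absolute_risk(bors, 0.5)
        assert np.all(np.diff(risks) > 0)
        assert absolute_risk(2.0, 0.3) < absolute_risk(2.0, 0.6)

    def test_matches_empirical_case_fraction(self, rng):
        # population with 12% prevalence; compare P(case | z in bin) at z
        n = 200_000
        prevalence = 0.12
        status = rng.random(n) < prevalence
        scores = np.where(status, rng.normal(0.8, 1.0, n), rng.normal(0.0, 1.0, n))
        s = fit_gaussian_summary(scores, status.astype(int))
        r = prevalence / (1 - prevalence)
        for z in (0.0, 1.0, 2.0):
            m = (scores >= z - 0.15) & (scores < z + 0.15)
            emp = status[m].mean()
            pred = absolute_risk(binned_odds_ratio(s, z), r)
            se = np.sqrt(emp * (1 - emp) / m.sum())
            assert abs(pred - emp) < 4 * se

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            absolute_risk(0.0, 1.0)
        with pytest.raises(ValueError):
            absolute_risk(1.0, -2.0)


class TestChi2Normality:
    def test_calibrated_rejection_rate_under_the_null(self):
        rng = np.random.default_rng(77)
        reps, alpha = 200, 0.05
        rejections = sum(
            chi2_normality(rng.standard_normal(10_000))[2] < alpha
            for _ in range(reps)
        )
        rate = rejections / reps
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rate - alpha) < 3 * se

    def test_power_against_heavy_tails(self, rng):
        scores = stats.t.rvs(df=2, size=10_000, random_state=rng)
        assert chi2_normality(scores)[2] < 1e-3

    def test_location_scale_invariance(self, rng):
        scores = rng.standard_normal(5_000)
        chi2_a, dof_a, _ = chi2_normality(scores)
        chi2_b, dof_b, _ = chi2_normality(2.0 * scores + 5.0)
        assert chi2_a == pytest.approx(chi2_b)
        assert dof_a == dof_b

    def test_sturges_bin_count_and_dof(self, rng):
        scores = rng.standard_normal(1_000)
        _, dof, _ = chi2_normality(scores)
        bins = int(np.ceil(1 + np.log2(1_000)))
        assert dof == bins - 3

    def test_too_small_sample_raises(self):
        with pytest.raises(ValueError):
            chi2_normality(np.arange(5.0))


class TestGaussianRiskModelEstimator:
    def test_fit_then_analytics(self, rng):
        scores = np.r_[rng.normal(1.0, 1.0, 2_000), rng.normal(0.0, 1.0, 8_000)]
        labels = np.r_[np.ones(2_000, int), np.zeros(8_000, int)]
        model = GaussianRiskModel(prevalence=0.12).fit(scores, labels)
        assert 0.7 < model.auc() < 0.8
        assert model.odds_ratio_tail(1.645) > 3
        assert 0 < model.absolute_risk(2.0) < 1
        assert model.density(0.0) > 0

    def test_params_roundtrip(self):
        m = GaussianRiskModel(prevalence=0.05)
        assert GaussianRiskModel(**m.get_params()).prevalence == 0.05
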