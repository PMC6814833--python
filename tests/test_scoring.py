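"""Polygenic score computation, covariate augmentation, regressand variants."""

import numpy as np
import pytest

from polyrisk import (
    augment_scores,
    compute_pgs,
    fit_covariate_model,
    transform_regressand,
)
from polyrisk.cohort import GenotypeMatrix, PhenotypeTable
from polyrisk.lasso import EffectModel
from polyrisk.scoring import CovariateModel, ScoreSet


def _matrix(dosages, ids=None):
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        variant_ids=ids or [f"v{j}" for j in range(p)],
        dosages=dosages,
        allele_freqs=dosages.mean(axis=0) / 2,
        chromosome_labels=["1"] * p,
    )


def _model(ids, beta, intercept=0.0):
    return EffectModel(variant_ids=ids, beta=np.asarray(beta, float),
                       intercept=intercept, lambda_value=1e-3)


class TestComputePgs:
    def test_hand_arithmetic(self):
        G = _matrix([[0, 2], [1, 1]])
        scores = compute_pgs(G, _model(["v0", "v1"], [0.5, -0.25]))
        np.testing.assert_allclose(scores.pgs, [-0.5, 0.25])

    def test_empty_model_yields_intercept(self):
        G = _matrix([[0, 2], [1, 1]])
        scores = compute_pgs(G, _model([], [], intercept=0.7))
        np.testing.assert_allclose(scores.pgs, [0.7, 0.7])

    def test_missing_variant_raises_then_skips_behind_flag(self):
        G = _matrix([[0.0], [1.0]])
        model = _model(["v0", "vX"], [1.0, 5.0])
        with pytest.raises(KeyError):
            compute_pgs(G, model)
        scores = compute_pgs(G, model, missing="skip")
        np.testing.assert_allclose(scores.pgs, [0.0, 1.0])

    def test_linearity_in_the_effect_model(self, rng):
        G = _matrix(rng.integers(0, 3, size=(20, 4)).astype(float))
        b1, b2 = rng.standard_normal(4), rng.standard_normal(4)
        s1 = compute_pgs(G, _model(G.variant_ids, b1, 0.3))
        s2 = compute_pgs(G, _model(G.variant_ids, b2, -0.1))
        s12 = compute_pgs(G, _model(G.variant_ids, b1 + b2, 0.2))
        np.testing.assert_allclose(s12.pgs, s1.pgs + s2.pgs, atol=1e-12)


class TestCovariateModel:
    def test_matches_closed_form_least_squares(self):
        pheno = PhenotypeTable(
            sample_ids=list("abcd"),
            status=[1, 0, 1, 0],
            sex=[0, 0, 1, 1],
            age=[40.0, 50.0, 60.0, 70.0],
        )
        cov = fit_covariate_model(pheno)
        D = np.column_stack([np.ones(4), pheno.sex, pheno.age])
        oracle = np.linalg.solve(D.T @ D, D.T @ pheno.status)
        np.testing.assert_allclose([cov.beta0, cov.beta_sex, cov.beta_age],
                                   oracle, rtol=1e-10)

    def test_null_covariates_give_near_zero_coefficients(self, rng):
        n = 10_000
        pheno = PhenotypeTable(
            sample_ids=[f"s{i}" for i in range(n)],
            status=rng.integers(0, 2, n),
            sex=rng.integers(0, 2, n),
            age=rng.uniform(40, 70, n),
        )
        cov = fit_covariate_model(pheno)
        D = np.column_stack([np.ones(n), pheno.sex, pheno.age])
        resid = pheno.status - D @ [cov.beta0, cov.beta_sex, cov.beta_age]
        sigma2 = resid @ resid / (n - 3)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(D.T @ D)))
        assert abs(cov.beta_sex) < 3 * se[1]
        assert abs(cov.beta_age) < 3 * se[2]

    def test_age_shift_moves_intercept_only(self):
        pheno = PhenotypeTable(sample_ids=list("abcd"), status=[0, 0, 1, 1],
                               sex=[0, 1, 0, 1], age=[40.0, 50.0, 60.0, 70.0])
        shifted = PhenotypeTable(sample_ids=list("abcd"), status=[0, 0, 1, 1],
                                 sex=[0, 1, 0, 1], age=[45.0, 55.0, 65.0, 75.0])
        a, b = fit_covariate_model(pheno), fit_covariate_model(shifted)
        fa = a.linear_predictor(pheno.sex, pheno.age)
        fb = b.linear_predictor(shifted.sex, shifted.age)
        np.testing.assert_allclose(fa, fb, atol=1e-9)
        assert a.beta0 != pytest.approx(b.beta0)

    def test_degenerate_design_raises(self):
        pheno = PhenotypeTable(sample_ids=list("ab"), status=[1, 0],
                               sex=[1, 1], age=[50.0, 50.0])
        with pytest.raises(ValueError):
            fit_covariate_model(pheno)


class TestAugmentScores:
    def _pheno(self, n, rng):
        return PhenotypeTable(
            sample_ids=[f"s{i}" for i in range(n)],
            status=rng.integers(0, 2, n),
            sex=rng.integers(0, 2, n),
            age=rng.uniform(40, 70, n),
        )

    def test_zero_covariate_model_is_identity(self, rng):
        pheno = self._pheno(10, rng)
        scores = ScoreSet(sample_ids=pheno.sample_ids, pgs=rng.standard_normal(10))
        out = augment_scores(scores, CovariateModel(0.0, 0.0, 0.0), pheno)
        np.testing.assert_array_equal(out.augmented, scores.pgs)

    def test_commutes_with_sample_permutation(self, rng):
        pheno = self._pheno(20, rng)
        pgs = rng.standard_normal(20)
        cov = CovariateModel(0.1, 0.4, -0.002)
        scores = ScoreSet(sample_ids=pheno.sample_ids, pgs=pgs)
        base = augment_scores(scores, cov, pheno).augmented
        perm = rng.permutation(20)
        p_pheno = pheno.subset(perm)
        p_scores = ScoreSet(sample_ids=p_pheno.sample_ids, pgs=pgs[perm])
        permuted = augment_scores(p_scores, cov, p_pheno).augmented
        np.testing.assert_allclose(permuted, base[perm])

    def test_sample_mismatch_raises(self, rng):
        pheno = self._pheno(5, rng)
        scores = ScoreSet(sample_ids=["x"] * 5, pgs=np.zeros(5))
        with pytest.raises(ValueError):
            augment_scores(scores, CovariateModel(0, 0, 0), pheno)


class TestTransformRegressand:
    def _pheno(self, rng, n=500):
        return PhenotypeTable(
            sample_ids=[f"s{i}" for i in range(n)],
            status=rng.integers(0, 2, n),
            sex=rng.integers(0, 2, n),
            age=rng.uniform(40, 70, n),
        )

    def test_cc_mode_is_identity(self, rng):
        pheno = self._pheno(rng)
        np.testing.assert_array_equal(transform_regressand(pheno, "cc"),
                                      pheno.status.astype(float))

    def test_mod1_residuals_orthogonal_to_covariates(self, rng):
        pheno = self._pheno(rng)
        y = transform_regressand(pheno, "mod1")
        # least-squares residuals are orthogonal to every design column
        assert abs(y.sum()) < 1e-8
        assert abs(y @ pheno.sex) < 1e-8
        assert abs(y @ pheno.age) < 1e-6

    def test_mod2_standardizes_within_sex(self, rng):
        pheno = self._pheno(rng)
        # reconstruct the intermediate standardized variable
        y = pheno.status.astype(float)
        for s in (0, 1):
            m = pheno.sex == s
            z = (y[m] - y[m].mean()) / y[m].std(ddof=0)
            assert z.mean() == pytest.approx(0.0, abs=1e-12)
            assert z.std(ddof=0) == pytest.approx(1.0, rel=1e-12)
        out = transform_regressand(pheno, "mod2")
        assert abs(out @ pheno.age) < 1e-6  # age regressed out

    def test_mod2_requires_both_sexes(self):
        pheno = PhenotypeTable(sample_ids=list("abcd"), status=[1, 0, 1, 0],
                               sex=[0, 0, 0, 0], age=[40.0, 50, 60, 70])
        with pytest.raises(ValueError):
            transform_regressand(pheno, "mod2")

    def test_unknown_mode_raises(self, rng):
        with pytest.raises(ValueError):
            transform_regressand(self._pheno(rng), "mod3")
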