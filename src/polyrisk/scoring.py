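"""Polygenic score computation, sex/age augmentation, and regressand variants.

The polygenic score is PGS_i = sum_j X_ij beta*_j (+ intercept), evaluated
on the same dosage scale the effect model was trained on. Because SNP state,
sex, and age are independent degrees of freedom, a separately fitted linear
model of status on (1, sex, age) can simply be added to the genetic score to
form an augmented predictor. Three regressand choices are supported for
training: raw case-control status, status minus the covariate fit
(modification 1), and within-sex standardized status minus an age fit
(modification 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import GenotypeMatrix, PhenotypeTable
from .lasso import EffectModel

__all__ = [
    "ScoreSet",
    "CovariateModel",
    "compute_pgs",
    "fit_covariate_model",
    "augment_scores",
    "transform_regressand",
]


@dataclass
class ScoreSet:
    sample_ids: list[str]
    pgs: np.ndarray
    augmented: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pgs = np.asarray(self.pgs, dtype=float)
        if len(self.sample_ids) != len(self.pgs):
            raise ValueError("one score per sample required")
        if not np.all(np.isfinite(self.pgs)):
            raise ValueError("scores must be finite")


@dataclass
class CovariateModel:
    """OLS of status on (1, sex, age), plus within-sex score moments."""

    beta0: float
    beta_sex: float
    beta_age: float
    sex_strata_means: tuple[float, float] | None = None  # (male=0, female=1)
    sex_strata_sds: tuple[float, float] | None = None

    def linear_predictor(self, sex: np.ndarray, age: np.ndarray) -> np.ndarray:
        return self.beta0 + self.beta_sex * np.asarray(sex) + self.beta_age * np.asarray(age)


def compute_pgs(G: GenotypeMatrix, model: EffectModel, missing: str = "error") -> ScoreSet:
    """PGS_i = sum_j X_ij beta_j + intercept over the model's variants.

    Variants in the model but absent from ``G`` raise by default;
    ``missing='skip'`` drops them (their contribution becomes zero).
    """
    pos = {v: j for j, v in enumerate(G.variant_ids)}
    cols, betas = [], []
    for v, b in zip(model.variant_ids, model.beta):
        j = pos.get(v)
        if j is None:
            if missing == "error":
                raise KeyError(f"model variant {v!r} not present in genotype matrix")
            continue
        cols.append(j)
        betas.append(b)
    if cols:
        scores = G.dosages[:, cols] @ np.asarray(betas) + model.intercept
    else:
        scores = np.full(G.n_samples, model.intercept)
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite polygenic scores")
    return ScoreSet(sample_ids=list(G.sample_ids), pgs=scores)


def fit_covariate_model(pheno: PhenotypeTable) -> CovariateModel:
    """Ordinary least squares of case-control status on (1, sex, age)."""
    sex = pheno.sex.astype(float)
    age = pheno.age
    if np.ptp(sex) == 0 and np.ptp(age) == 0:
        raise ValueError("degenerate design: single sex and single age")
    D = np.column_stack([np.ones_like(age), sex, age])
    coef, *_ = np.linalg.lstsq(D, pheno.status.astype(float), rcond=None)
    return CovariateModel(beta0=float(coef[0]), beta_sex=float(coef[1]),
                          beta_age=float(coef[2]))


def augment_scores(scores: ScoreSet, cov: CovariateModel, pheno: PhenotypeTable) -> ScoreSet:
    """Add the covariate linear predictor to each genetic score."""
    if scores.sample_ids != pheno.sample_ids:
        raise ValueError("score and phenotype sample ids do not match")
    aug = scores.pgs + cov.linear_predictor(pheno.sex, pheno.age)
    return ScoreSet(sample_ids=list(scores.sample_ids), pgs=scores.pgs, augmented=aug)


def transform_regressand(pheno: PhenotypeTable, mode: str = "cc") -> np.ndarray:
    """Training regressand y' under the three supported modifications.

    - ``cc``:   y' = y (case-control status unchanged).
    - ``mod1``: y' = y - (b0 + bS*sex + bAge*age), coefficients freshly fit.
    - ``mod2``: standardize y to mean 0 / SD 1 within each sex stratum, then
      subtract a fresh regression of that variable on (1, age).
    """
    y = pheno.status.astype(float)
    if mode == "cc":
        return y.copy()
    if mode == "mod1":
        cov = fit_covariate_model(pheno)
        return y - cov.linear_predictor(pheno.sex, pheno.age)
    if mode == "mod2":
        sexes = np.unique(pheno.sex)
        if len(sexes) < 2:
            raise ValueError("modification 2 requires both sexes present")
        ystd = np.empty_like(y)
        for s in sexes:
            m = pheno.sex == s
            sd = y[m].std(ddof=0)
            if sd == 0:
                raise ValueError(f"zero status variance within sex stratum {s}")
            ystd[m] = (y[m] - y[m].mean()) / sd
        D = np.column_stack([np.ones_like(pheno.age), pheno.age])
        coef, *_ = np.linalg.lstsq(D, ystd, rcond=None)
        return ystd - D @ coef
    raise ValueError("mode must be one of 'cc', 'mod1', 'mod2'")
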