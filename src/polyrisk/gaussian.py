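"""Displaced-Gaussian risk calculus for polygenic score distributions.

Case and control polygenic scores are modeled as two overlapping normal
distributions N(mu1, sigma1^2) and N(mu0, sigma0^2). Under that assumption
the AUC, the tail odds ratio OR(z), the binned odds ratio BOR(z) = f1/f0,
and cross-population absolute risk all have closed forms:

    AUC    = Phi((mu1 - mu0) / sqrt(sigma1^2 + sigma0^2))
    OR(z)  = Phibar((z - mu1)/sigma1) / Phibar((z - mu0)/sigma0)
    P(case | z) = 1 / (1 + 1/(r * BOR(z)))       r = N1/N0 in the target pop

where Phi is the standard normal CDF and Phibar its complement (evaluated
directly via the survival function, so the deep tail is numerically stable).
BOR is independent of a sub-population's case/control ratio, which is what
lets absolute risk computed in a test cohort be translated to any population
with known prevalence. A chi-squared goodness-of-fit test with Sturges'
bin-count rule checks the normality assumption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "GaussianSummary",
    "RiskTranslation",
    "fit_gaussian_summary",
    "auc_gaussian",
    "odds_ratio_tail",
    "population_score_density",
    "binned_odds_ratio",
    "absolute_risk",
    "chi2_normality",
    "GaussianRiskModel",
]


@dataclass
class GaussianSummary:
    """(mean, SD, count) of the score distribution for cases and controls."""

    mu_case: float
    mu_control: float
    sigma_case: float
    sigma_control: float
    n_case: int = 2
    n_control: int = 2

    def __post_init__(self) -> None:
        if self.sigma_case <= 0 or self.sigma_control <= 0:
            raise ValueError("stratum standard deviations must be > 0")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 samples per stratum")

    @property
    def case_control_ratio(self) -> float:
        return self.n_case / self.n_control


@dataclass
class RiskTranslation:
    """Absolute risk at a score value, translated via the shared BOR."""

    z: float
    bor: float
    r: float
    prob_case: float


def fit_gaussian_summary(scores, labels) -> GaussianSummary:
    """Stratum sample means and sample SDs (n-1 denominator) with counts."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError("need at least 2 cases and 2 controls")
    s1 = cases.std(ddof=1)
    s0 = controls.std(ddof=1)
    if s1 == 0 or s0 == 0:
        raise ValueError("degenerate stratum: zero score variance")
    return GaussianSummary(
        mu_case=float(cases.mean()),
        mu_control=float(controls.mean()),
        sigma_case=float(s1),
        sigma_control=float(s0),
        n_case=len(cases),
        n_control=len(controls),
    )


def auc_gaussian(summary: GaussianSummary) -> float:
    """Analytic AUC of two displaced normals."""
    d = summary.mu_case - summary.mu_control
    s = np.hypot(summary.sigma_case, summary.sigma_control)
    return float(stats.norm.cdf(d / s))


def odds_ratio_tail(summary: GaussianSummary, z) -> np.ndarray | float:
    """OR(z): tail case/control odds above z relative to population odds."""
    z = np.asarray(z, dtype=float)
    num = stats.norm.sf((z - summary.mu_case) / summary.sigma_case)
    den = stats.norm.sf((z - summary.mu_control) / summary.sigma_control)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    return float(out) if out.ndim == 0 else out


def population_score_density(summary: GaussianSummary, z) -> np.ndarray | float:
    """Mixture density (N1 f1 + N0 f0) / (N1 + N0) of the pooled population."""
    z = np.asarray(z, dtype=float)
    f1 = stats.norm.pdf(z, summary.mu_case, summary.sigma_case)
    f0 = stats.norm.pdf(z, summary.mu_control, summary.sigma_control)
    n1, n0 = summary.n_case, summary.n_control
    out = (n1 * f1 + n0 * f0) / (n1 + n0)
    return float(out) if out.ndim == 0 else out


def binned_odds_ratio(summary: GaussianSummary, z) -> np.ndarray | float:
    """BOR(z) = f1(z) / f0(z): case-to-control density ratio at score z.

    Independent of the sub-population's case/control counts, so it transfers
    between populations that share the score distributions.
    """
    z = np.asarray(z, dtype=float)
    # evaluate on the log scale; stable far into either tail
    log_f1 = stats.norm.logpdf(z, summary.mu_case, summary.sigma_case)
    log_f0 = stats.norm.logpdf(z, summary.mu_control, summary.sigma_control)
    out = np.exp(log_f1 - log_f0)
    return float(out) if out.ndim == 0 else out


def absolute_risk(bor, r) -> np.ndarray | float:
    """P(case | z) = 1 / (1 + 1/(r * BOR)) for case/control ratio r."""
    bor = np.asarray(bor, dtype=float)
    if np.any(bor <= 0):
        raise ValueError("BOR must be > 0")
    if r <= 0:
        raise ValueError("case/control ratio r must be > 0")
    out = 1.0 / (1.0 + 1.0 / (r * bor))
    return float(out) if out.ndim == 0 else out


def chi2_normality(scores, dof_adjust: int = 2) -> tuple[float, int, float]:
    """Chi-squared normality test with Sturges' rule for the bin count.

    Bins = ceil(1 + log2 n) equal-probability bins under the fitted
    N(mean, sd); dof = bins - 1 - dof_adjust (default 2 for the two fitted
    parameters). Returns (chi2, dof, upper-tail p).
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if n < 8:
        raise ValueError("need at least 8 observations")
    n_bins = int(np.ceil(1 + np.log2(n)))
    expected = n / n_bins
    if expected < 1:
        raise ValueError("expected count below 1; use fewer bins")
    mu, sd = scores.mean(), scores.std(ddof=1)
    edges = stats.norm.ppf(np.linspace(0, 1, n_bins + 1), mu, sd)
    observed, _ = np.histogram(scores, bins=edges)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    dof = n_bins - 1 - dof_adjust
    p = float(stats.chi2.sf(chi2, dof))
    return chi2, dof, p


class GaussianRiskModel(BaseEstimator):
    """Sklearn-style wrapper over the displaced-Gaussian analytics.

    ``fit(scores, labels)`` estimates the case/control Gaussian summary;
    the analytic quantities are then available as methods. ``prevalence``
    (optional) sets the case/control ratio used by :meth:`predict_proba`-style
    absolute risk in a target population; default uses the fitted counts.
    """

    def __init__(self, prevalence: float | None = None):
        self.prevalence = prevalence

    def fit(self, scores, labels):
        self.summary_ = fit_gaussian_summary(scores, labels)
        return self

    def _r(self) -> float:
        if self.prevalence is not None:
            return self.prevalence / (1 - self.prevalence)
        return self.summary_.case_control_ratio

    def auc(self) -> float:
        return auc_gaussian(self.summary_)

    def odds_ratio_tail(self, z):
        return odds_ratio_tail(self.summary_, z)

    def absolute_risk(self, z, r: float | None = None):
        bor = binned_odds_ratio(self.summary_, z)
        return absolute_risk(bor, self._r() if r is None else r)

    def density(self, z):
        return population_score_density(self.summary_, z)
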