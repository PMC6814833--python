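"""Sample-size scaling of AUC and the cost-benefit calculator.

Across training runs with increasing case counts, the test-set AUC grows
roughly linearly in log N. Fitting AUC against log(N/1000) by ordinary least
squares gives a line that can be extrapolated to hypothetical future cohort
sizes. A separate helper evaluates the per-individual financial balance of
population genotyping: X = sum_i T_i (F_i B_i - C_i) - G, where condition
terms that come out negative are simply not used (floored at zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "ScalingFit",
    "CostBenefitParams",
    "ConditionParams",
    "fit_auc_scaling",
    "extrapolate_auc",
    "cost_benefit",
    "AucScaling",
]


@dataclass
class ScalingFit:
    """OLS line of AUC on log(n_cases/1000) (natural log internally)."""

    points: list[tuple[int, float]]
    slope: float
    intercept: float

    def predict(self, n_cases) -> np.ndarray | float:
        n = np.asarray(n_cases, dtype=float)
        out = self.intercept + self.slope * np.log(n / 1000.0)
        return float(out) if out.ndim == 0 else out


@dataclass
class ConditionParams:
    """One disease condition's screening economics."""

    T: float  # population fraction above the score cutoff, in (0, 1]
    F: float  # fraction of those who develop the condition, in [0, 1]
    B: float  # benefit of early detection per developing individual
    C: float  # cost of the intervention per flagged individual

    def __post_init__(self) -> None:
        if not 0 < self.T <= 1:
            raise ValueError("T must lie in (0, 1]")
        if not 0 <= self.F <= 1:
            raise ValueError("F must lie in [0, 1]")
        if self.B < 0 or self.C < 0:
            raise ValueError("B and C must be nonnegative")


@dataclass
class CostBenefitParams:
    genotyping_cost: float
    conditions: list[ConditionParams] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.genotyping_cost < 0:
            raise ValueError("genotyping cost must be nonnegative")


def fit_auc_scaling(points) -> ScalingFit:
    """Least squares of AUC on log(n_cases/1000) over (n_cases, auc) pairs."""
    pts = [(int(n), float(a)) for n, a in points]
    ns = np.array([n for n, _ in pts], dtype=float)
    if len(pts) < 2 or len(np.unique(ns)) < 2:
        raise ValueError("need at least 2 points with distinct case counts")
    aucs = np.array([a for _, a in pts])
    x = np.log(ns / 1000.0)
    slope, intercept = np.polyfit(x, aucs, 1)
    return ScalingFit(points=pts, slope=float(slope), intercept=float(intercept))


def extrapolate_auc(fit: ScalingFit, n_target: int, truncate_2dp: bool = False) -> float:
    """Fitted line evaluated at n_target cases.

    ``truncate_2dp`` floors the value to 2 decimals for presentation
    (a tiny epsilon guards against representation error at exact hundredths).
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    value = float(fit.predict(n_target))
    if truncate_2dp:
        return math.floor(value * 100 + 1e-9) / 100
    return value


def cost_benefit(params: CostBenefitParams) -> tuple[float, list[float]]:
    """Per-person net benefit X and the raw per-condition terms.

    Each condition contributes T(FB - C); negative contributions are floored
    to zero (the condition is simply not screened for) before subtracting
    the genotyping cost G. The raw, unfloored terms are returned alongside X.
    """
    raw = [c.T * (c.F * c.B - c.C) for c in params.conditions]
    x = sum(max(t, 0.0) for t in raw) - params.genotyping_cost
    return float(x), raw


class AucScaling(BaseEstimator, RegressorMixin):
    """Sklearn-style regressor: AUC as a linear function of log(N/1000).

    ``fit(n_cases, auc)`` with 1-D arrays; ``predict(n_cases)`` evaluates the
    line. Attributes ``slope_`` and ``intercept_`` expose the fit.
    """

    def fit(self, n_cases, auc):
        sf = fit_auc_scaling(list(zip(np.ravel(n_cases), np.ravel(auc))))
        self.slope_ = sf.slope
        self.intercept_ = sf.intercept
        self.scaling_fit_ = sf
        return self

    def predict(self, n_cases):
        return self.scaling_fit_.predict(np.ravel(n_cases))
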