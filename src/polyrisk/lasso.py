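"""L1-penalized linear regression by cyclic coordinate descent.

The objective is

    O_lambda(beta) = 1/2 ||y - X beta||^2 + n * lambda * ||beta||_1

with n the sample count — note the n multiplying the penalty, which makes
lambda values comparable across cohort sizes. The solver cycles coordinates
with the soft-threshold update, warm-starts along a decreasing lambda grid,
and recovers the intercept through centering (the intercept is never
penalized). Columns are centered and, by default, scaled to unit population
standard deviation before fitting; coefficients are mapped back to the
dosage scale on output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "EffectModel",
    "LambdaPath",
    "lasso_objective",
    "soft_threshold",
    "coordinate_descent",
    "fit_lambda_path",
    "lambda_max",
    "kkt_violation",
    "PgsLasso",
]


@dataclass
class EffectModel:
    """Sparse per-variant effects on the dosage scale, plus intercept."""

    variant_ids: list[str]
    beta: np.ndarray
    intercept: float
    lambda_value: float
    col_means: np.ndarray | None = None
    col_scales: np.ndarray | None = None
    objective_history: np.ndarray = field(default=None, repr=False)
    n_sweeps: int = 0

    @property
    def n_active(self) -> int:
        return int(np.count_nonzero(self.beta))


@dataclass
class LambdaPath:
    """Solutions along a strictly decreasing lambda grid."""

    lambdas: np.ndarray
    models: list[EffectModel]
    objective_values: np.ndarray  # objective in the (centered/scaled) fit space

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lambdas) >= 0):
            raise ValueError("lambdas must be strictly decreasing")


def lasso_objective(y: np.ndarray, X: np.ndarray, beta: np.ndarray, lam: float) -> float:
    """Evaluate 1/2 ||y - X beta||^2 + n*lambda*||beta||_1 exactly as written."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if X.shape[0] != len(y) or X.shape[1] != len(beta):
        raise ValueError("dimension mismatch between y, X and beta")
    r = y - X @ beta
    n = len(y)
    return 0.5 * float(r @ r) + n * lam * float(np.abs(beta).sum())


def soft_threshold(x: float, t: float) -> float:
    """S(x, t) = sign(x) * max(|x| - t, 0)."""
    return float(np.sign(x) * max(abs(x) - t, 0.0))


@njit(cache=True)
def _cd_kernel(Xf, y, beta, colsq, lam_n, tol, max_sweeps, objectives):  # pragma: no cover
    n, p = Xf.shape
    r = y - Xf @ beta
    sweeps = 0
    for sweep in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            if colsq[j] <= 0.0:
                continue
            bj = beta[j]
            rho = 0.0
            for i in range(n):
                rho += Xf[i, j] * r[i]
            rho += colsq[j] * bj
            if rho > lam_n:
                bnew = (rho - lam_n) / colsq[j]
            elif rho < -lam_n:
                bnew = (rho + lam_n) / colsq[j]
            else:
                bnew = 0.0
            d = bnew - bj
            if d != 0.0:
                for i in range(n):
                    r[i] -= Xf[i, j] * d
                beta[j] = bnew
                ad = abs(d)
                if ad > max_delta:
                    max_delta = ad
        rss = 0.0
        for i in range(n):
            rss += r[i] * r[i]
        l1 = 0.0
        for j in range(p):
            l1 += abs(beta[j])
        objectives[sweep] = 0.5 * rss + lam_n * l1
        sweeps = sweep + 1
        if max_delta < tol:
            break
    return sweeps


def _prepare(X: np.ndarray, y: np.ndarray, standardize: bool):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite entries in X or y")
    means = X.mean(axis=0)
    Xc = X - means
    if standardize:
        scales = Xc.std(axis=0)  # population SD
        scales = np.where(scales > 0, scales, 1.0)
    else:
        scales = np.ones(X.shape[1])
    Xf = np.asfortranarray(Xc / scales)
    ym = y.mean()
    return Xf, y - ym, ym, means, scales


def lambda_max(X: np.ndarray, y: np.ndarray, standardize: bool = True) -> float:
    """Smallest lambda at which the solution is exactly zero."""
    Xf, yc, _, _, _ = _prepare(X, y, standardize)
    return float(np.abs(Xf.T @ yc).max() / len(yc))


def coordinate_descent(
    y: np.ndarray,
    X: np.ndarray,
    lam: float,
    beta_init: np.ndarray | None = None,
    tol: float = 1e-7,
    max_sweeps: int = 1000,
    standardize: bool = True,
    variant_ids: list[str] | None = None,
) -> EffectModel:
    """Minimize the penalized objective at a fixed lambda.

    Returns an :class:`EffectModel` with coefficients on the dosage scale and
    the per-sweep objective history (computed in the centered/scaled fit
    space; non-increasing by construction of the coordinate updates).
    """
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    Xf, yc, ym, means, scales = _prepare(X, y, standardize)
    n, p = Xf.shape
    beta = np.zeros(p) if beta_init is None else np.array(beta_init, dtype=float)
    colsq = np.einsum("ij,ij->j", Xf, Xf)
    objectives = np.empty(max_sweeps)
    sweeps = _cd_kernel(Xf, yc, beta, colsq, n * lam, tol, max_sweeps, objectives)

    beta_dosage = beta / scales
    intercept = ym - float(means @ beta_dosage)
    ids = variant_ids or [f"v{j}" for j in range(p)]
    return EffectModel(
        variant_ids=list(ids),
        beta=beta_dosage,
        intercept=intercept,
        lambda_value=lam,
        col_means=means,
        col_scales=scales,
        objective_history=objectives[:sweeps].copy(),
        n_sweeps=sweeps,
    )


def kkt_violation(y: np.ndarray, X: np.ndarray, model: EffectModel, standardize: bool = True) -> float:
    """Largest violation of the stationarity conditions, in fit-space units.

    At an exact minimizer, |X_j' r| = n*lambda for active coordinates and
    <= n*lambda for inactive ones; returns the worst excess over those
    bounds (0 means the conditions hold exactly).
    """
    Xf, yc, _, _, _ = _prepare(X, y, standardize)
    n = Xf.shape[0]
    beta_fit = model.beta * (model.col_scales if model.col_scales is not None else 1.0)
    r = yc - Xf @ beta_fit
    grad = Xf.T @ r
    lam_n = n * model.lambda_value
    active = beta_fit != 0
    v_active = np.abs(np.abs(grad[active]) - lam_n) if active.any() else np.array([0.0])
    v_inactive = np.clip(np.abs(grad[~active]) - lam_n, 0, None) if (~active).any() else np.array([0.0])
    return float(max(v_active.max(), v_inactive.max()))


def fit_lambda_path(
    y: np.ndarray,
    X: np.ndarray,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
    tol: float = 1e-7,
    max_sweeps: int = 1000,
    standardize: bool = True,
    variant_ids: list[str] | None = None,
) -> LambdaPath:
    """Warm-started solutions along a log-spaced decreasing lambda grid.

    The grid runs from lambda_max (where the solution is exactly zero) down
    to lambda_max * lambda_min_ratio; each fit starts from the previous
    solution.
    """
    if n_lambdas < 2:
        raise ValueError("need at least 2 lambda values")
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("X is empty")
    lmax = lambda_max(X, y, standardize)
    if lmax <= 0:
        raise ValueError("lambda_max is zero; y is orthogonal to every column")
    lambdas = np.geomspace(lmax, lmax * lambda_min_ratio, n_lambdas)

    Xf, yc, _, _, _ = _prepare(X, y, standardize)
    models: list[EffectModel] = []
    objective_values = np.empty(n_lambdas)
    warm: np.ndarray | None = None
    for i, lam in enumerate(lambdas):
        m = coordinate_descent(
            y, X, lam,
            beta_init=warm,
            tol=tol,
            max_sweeps=max_sweeps,
            standardize=standardize,
            variant_ids=variant_ids,
        )
        warm = m.beta * (m.col_scales if m.col_scales is not None else 1.0)
        models.append(m)
        objective_values[i] = m.objective_history[-1]
    return LambdaPath(lambdas=lambdas, models=models, objective_values=objective_values)


class PgsLasso(BaseEstimator, RegressorMixin):
    """Sparse linear predictor for case-control polygenic scores.

    Coordinate-descent solver for 1/2||y - Xb||^2 + n*lam*||b||_1 with an
    unpenalized intercept.

    Parameters
    ----------
    lam : float
        Penalty strength (the lambda of the objective).
    standardize : bool
        Center and unit-scale columns before fitting (default). Coefficients
        are always reported on the input scale.
    tol : float
        Convergence threshold on the largest coefficient change per sweep.
    max_sweeps : int
        Hard cap on coordinate sweeps.

    Attributes
    ----------
    coef_ : ndarray
        Per-column effects on the input scale.
    intercept_ : float
    n_active_ : int
        Count of nonzero coefficients.
    n_iter_ : int
        Sweeps performed.
    """

    def __init__(self, lam: float = 1e-3, standardize: bool = True,
                 tol: float = 1e-7, max_sweeps: int = 1000):
        self.lam = lam
        self.standardize = standardize
        self.tol = tol
        self.max_sweeps = max_sweeps

    def fit(self, X, y):
        model = coordinate_descent(
            np.asarray(y, dtype=float),
            np.asarray(X, dtype=float),
            self.lam,
            tol=self.tol,
            max_sweeps=self.max_sweeps,
            standardize=self.standardize,
        )
        self.coef_ = model.beta
        self.intercept_ = model.intercept
        self.n_active_ = model.n_active
        self.n_iter_ = model.n_sweeps
        self.effect_model_ = model
        return self

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_
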