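"""Penalty selection on non-overlapping holdback sets.

Five disjoint case/control holdback sets are carved out of the cohort; every
point of the lambda path is scored on each holdback by AUC; the selected
penalty is the per-fold best-AUC lambda, averaged across folds, shifted one
standard deviation toward *more* penalization (larger lambda), which errs on
the side of parsimony. Snap-to-grid picks the nearest grid lambda at or
above the shifted value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import GenotypeMatrix, PhenotypeTable, ascertain_case_control
from .lasso import LambdaPath
from .metrics import auc_mann_whitney

__all__ = [
    "CvDesign",
    "SelectionResult",
    "make_cv_design",
    "select_lambda_star",
    "evaluate_path_on_folds",
    "choose_grid_index",
]


@dataclass
class CvDesign:
    """Disjoint holdback index sets plus the residual training set."""

    holdback_sets: list[np.ndarray]
    training_idx: np.ndarray

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for s in self.holdback_sets:
            ss = set(int(i) for i in s)
            if seen & ss:
                raise ValueError("holdback sets overlap")
            seen |= ss
        if seen & set(int(i) for i in self.training_idx):
            raise ValueError("training set overlaps a holdback set")


@dataclass
class SelectionResult:
    per_fold_best: np.ndarray
    lambda_star: float
    lambda_star_sd: float
    scale: str = "linear"


def make_cv_design(
    pheno: PhenotypeTable,
    n_folds: int = 5,
    n_cases_hold: int = 1000,
    n_controls_hold: int = 1000,
    seed: int = 0,
    pool: np.ndarray | None = None,
) -> CvDesign:
    """Draw ``n_folds`` disjoint stratified holdback sets; the rest trains.

    ``pool`` restricts the design to a subset of samples (e.g. one ancestry
    group); raises with the deficit named if any stratum runs short.
    """
    pool = np.arange(pheno.n_samples) if pool is None else np.asarray(pool)
    remaining = pool.copy()
    holdbacks = []
    for fold in range(n_folds):
        idx = ascertain_case_control(
            pheno, n_cases_hold, n_controls_hold, seed=seed + fold, pool=remaining
        )
        holdbacks.append(idx)
        remaining = np.setdiff1d(remaining, idx)
    if remaining.size == 0:
        raise ValueError("no samples left for training after holdback draws")
    return CvDesign(holdback_sets=holdbacks, training_idx=remaining)


def select_lambda_star(per_fold_best, scale: str = "linear") -> SelectionResult:
    """Mean of per-fold best lambdas plus one sample SD (more penalization).

    ``scale='log'`` takes mean and SD on log10(lambda) and maps back — the
    path grid is log-spaced, so both readings are defensible; linear is the
    default.
    """
    best = np.asarray(per_fold_best, dtype=float)
    if best.size < 2:
        raise ValueError("need at least 2 folds to form a standard deviation")
    if np.any(best <= 0):
        raise ValueError("lambdas must be positive")
    if scale == "linear":
        sd = float(best.std(ddof=1))
        star = float(best.mean() + sd)
    elif scale == "log":
        lg = np.log10(best)
        sd_log = float(lg.std(ddof=1))
        star = float(10 ** (lg.mean() + sd_log))
        sd = sd_log
    else:
        raise ValueError("scale must be 'linear' or 'log'")
    return SelectionResult(per_fold_best=best, lambda_star=star,
                           lambda_star_sd=sd, scale=scale)


def evaluate_path_on_folds(
    path: LambdaPath,
    G: GenotypeMatrix,
    pheno: PhenotypeTable,
    design: CvDesign,
) -> np.ndarray:
    """AUC of each path model's score on each holdback set (folds x lambdas)."""
    train = set(int(i) for i in design.training_idx)
    for s in design.holdback_sets:
        if train & set(int(i) for i in s):
            raise ValueError("holdback set overlaps the training set")

    # dosage-scale betas stacked once; scores for all lambdas in one product
    B = np.column_stack([m.beta for m in path.models])
    intercepts = np.array([m.intercept for m in path.models])
    auc = np.empty((len(design.holdback_sets), len(path.lambdas)))
    for f, idx in enumerate(design.holdback_sets):
        scores = G.dosages[idx] @ B + intercepts
        labels = pheno.status[idx]
        for i in range(scores.shape[1]):
            auc[f, i] = auc_mann_whitney(scores[:, i], labels)
    return auc


def choose_grid_index(path: LambdaPath, lambda_star: float) -> int:
    """Nearest grid lambda at or above lambda_star (toward parsimony)."""
    lambdas = path.lambdas  # strictly decreasing
    at_or_above = np.flatnonzero(lambdas >= lambda_star)
    if at_or_above.size == 0:
        return 0  # lambda_star exceeds the grid top; most penalized point
    return int(at_or_above[-1])


def best_lambda_per_fold(path: LambdaPath, auc_by_lambda: np.ndarray) -> np.ndarray:
    """Lambda maximizing AUC in each fold (first/largest lambda on ties)."""
    return path.lambdas[np.argmax(auc_by_lambda, axis=1)]
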