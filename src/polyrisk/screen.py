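"""Single-marker association screening.

Before the penalized fit, each SNP is regressed individually against
case-control status and the markers are ranked by p-value; only the top-k
enter the multivariate model. The per-marker model is ordinary least squares
of y on dosage with an intercept (the linear treatment of a 0/1 phenotype),
with a two-sided p-value from the slope's t statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import GenotypeMatrix

DEFAULT_TOP_K = 50_000

__all__ = ["MarkerStats", "single_marker_regression", "select_top_k", "MarkerScreen"]


@dataclass
class MarkerStats:
    """Per-variant OLS slope, standard error and p-value.

    Monomorphic variants (zero dosage variance) are flagged degenerate and
    carry slope 0 and p = 1; they never survive ranking.
    """

    variant_ids: list[str]
    slopes: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    degenerate: np.ndarray  # bool per variant

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "slope": self.slopes,
                "se": self.standard_errors,
                "p_value": self.p_values,
                "degenerate": self.degenerate,
            }
        )


def single_marker_regression(G: GenotypeMatrix, y: np.ndarray) -> MarkerStats:
    """OLS of status on each dosage column separately, with intercept."""
    y = np.asarray(y, dtype=float)
    X = G.dosages
    n = X.shape[0]
    if len(y) != n:
        raise ValueError("status vector length does not match genotype rows")
    if n < 3:
        raise ValueError("need at least 3 samples for a per-marker t test")
    if np.ptp(y) == 0:
        raise ValueError("status is constant; nothing to regress")

    xm = X.mean(axis=0)
    ym = y.mean()
    xc = X - xm
    sxx = np.einsum("ij,ij->j", xc, xc)
    sxy = xc.T @ (y - ym)
    syy = float(((y - ym) ** 2).sum())

    degenerate = sxx <= 0
    sxx_safe = np.where(degenerate, 1.0, sxx)
    slope = np.where(degenerate, 0.0, sxy / sxx_safe)

    # residual sum of squares of the per-marker simple regression
    rss = syy - slope**2 * sxx
    rss = np.clip(rss, 0.0, None)
    dof = n - 2
    se = np.sqrt(rss / dof / sxx_safe)
    se = np.where(degenerate, 0.0, se)

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, slope / se, 0.0)
    p = 2 * stats.t.sf(np.abs(tstat), dof)
    p = np.where(degenerate, 1.0, np.clip(p, np.finfo(float).tiny, 1.0))

    return MarkerStats(
        variant_ids=list(G.variant_ids),
        slopes=slope,
        standard_errors=se,
        p_values=p,
        degenerate=degenerate,
    )


def select_top_k(marker_stats: MarkerStats, k: int = DEFAULT_TOP_K) -> list[str]:
    """Variant ids of the k smallest p-values, ascending, ties by index.

    Degenerate (monomorphic) variants are excluded before ranking; the result
    has min(k, number of usable variants) entries.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    usable = np.flatnonzero(~marker_stats.degenerate)
    # stable mergesort keeps ascending-variant-index tie order
    order = usable[np.argsort(marker_stats.p_values[usable], kind="stable")]
    return [marker_stats.variant_ids[j] for j in order[:k]]


class MarkerScreen(BaseEstimator, TransformerMixin):
    """Top-k marker selector usable inside an sklearn pipeline.

    Parameters
    ----------
    k : int
        Number of markers to keep (capped at the usable marker count).

    Attributes
    ----------
    marker_stats_ : MarkerStats
        Per-variant regression statistics from :func:`single_marker_regression`.
    selected_idx_ : ndarray of int
        Column indices of the selected markers, in rank order.
    """

    def __init__(self, k: int = DEFAULT_TOP_K):
        self.k = k

    def fit(self, X, y, variant_ids: list[str] | None = None):
        if isinstance(X, GenotypeMatrix):
            G = X
        else:
            X = np.asarray(X, dtype=float)
            ids = variant_ids or [f"v{j}" for j in range(X.shape[1])]
            G = GenotypeMatrix(
                sample_ids=[f"s{i}" for i in range(X.shape[0])],
                variant_ids=ids,
                dosages=np.clip(X, 0, 2),
                allele_freqs=X.mean(axis=0) / 2,
                chromosome_labels=["1"] * X.shape[1],
            )
        self.marker_stats_ = single_marker_regression(G, y)
        selected = select_top_k(self.marker_stats_, self.k)
        pos = {v: j for j, v in enumerate(G.variant_ids)}
        self.selected_ids_ = selected
        self.selected_idx_ = np.array([pos[v] for v in selected], dtype=int)
        return self

    def transform(self, X):
        if isinstance(X, GenotypeMatrix):
            return X.subset_variants(self.selected_ids_)
        return np.asarray(X)[:, self.selected_idx_]
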