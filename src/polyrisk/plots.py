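"""Diagnostic plots: ROC, case/control score histograms, OR vs percentile."""

from __future__ import annotations

import numpy as np

from .gaussian import GaussianSummary, odds_ratio_tail
from .metrics import ORCurve, ROCCurve

__all__ = ["plot_roc", "plot_score_histograms", "plot_or_curve"]


def _axes(ax):
    if ax is None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_roc(roc: ROCCurve, ax=None, label: str | None = None):
    ax = _axes(ax)
    ax.plot(roc.fpr, roc.tpr, label=label or f"AUC = {roc.auc_exact:.3f}")
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend()
    return ax


def plot_score_histograms(scores, labels, ax=None, bins: int = 40):
    """Overlaid control (blue) and case (gold) score histograms."""
    ax = _axes(ax)
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    ax.hist(scores[labels == 0], bins=bins, alpha=0.6, color="tab:blue",
            density=True, label="controls")
    ax.hist(scores[labels == 1], bins=bins, alpha=0.6, color="goldenrod",
            density=True, label="cases")
    ax.set_xlabel("polygenic score")
    ax.set_ylabel("density")
    ax.legend()
    return ax


def plot_or_curve(curve: ORCurve, summary: GaussianSummary | None = None, ax=None):
    """Empirical OR with Poisson error bars; analytic overlay if given."""
    ax = _axes(ax)
    ok = ~curve.undefined
    yerr = np.vstack([
        curve.or_values[ok] - curve.ci_low[ok],
        curve.ci_high[ok] - curve.or_values[ok],
    ])
    ax.errorbar(curve.percentiles[ok], curve.or_values[ok], yerr=yerr,
                fmt="o", ms=3, capsize=2, label="empirical")
    if summary is not None:
        ax.plot(curve.percentiles, odds_ratio_tail(summary, curve.thresholds),
                c="red", label="displaced-Gaussian")
    ax.set_xlabel("score percentile cutoff")
    ax.set_ylabel("odds ratio above cutoff")
    ax.legend()
    return ax
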