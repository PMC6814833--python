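"""End-to-end reproducible runs: simulate, screen, train, select, evaluate.

One run, per seed: generate a two-ancestry cohort, carve out a same-ancestry
test set and five disjoint holdback sets, screen markers on the training
samples only, fit the penalty path, select the penalty by the holdback rule,
and evaluate the chosen predictor on the untouched test sets (same ancestry
and the drifted "adjacent ancestry" subpopulation). Across-seed means and
standard deviations are reported, with each metric's error taken as the
larger of the seed SD and the binned-AUC precision bound.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .cohort import ascertain_case_control, simulate_genotypes, simulate_phenotypes
from .gaussian import auc_gaussian, chi2_normality, fit_gaussian_summary
from .lasso import fit_lambda_path
from .metrics import auc_mann_whitney, or_by_percentile, roc_binned
from .scoring import augment_scores, compute_pgs, fit_covariate_model, transform_regressand
from .screen import MarkerScreen
from .select import (
    best_lambda_per_fold,
    choose_grid_index,
    evaluate_path_on_folds,
    make_cv_design,
    select_lambda_star,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "scaling_experiment"]

#: precision of the binned ROC integration; error bars never fall below this
BINNED_AUC_PRECISION = 0.01


@dataclass
class RunConfig:
    """Cohort, screening, path, and evaluation settings for one run."""

    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    # cohort
    n_samples: int = 20_000
    n_variants: int = 2_000
    n_causal: int = 50
    heritability: float = 0.5
    prevalence: float = 0.12
    fst: float = 0.01
    subpop_fractions: tuple[float, float] = (0.85, 0.15)
    maf_range: tuple[float, float] = (0.05, 0.5)
    sex_effect: float = 0.0
    age_effect: float = 0.0
    # screening / path
    top_k: int = 500
    n_lambdas: int = 30
    lambda_min_ratio: float = 0.01
    # design
    n_folds: int = 5
    n_cases_hold: int = 150
    n_controls_hold: int = 150
    n_cases_test: int = 300
    n_controls_test: int = 300
    # scoring
    regressand: str = "cc"
    augment: bool = False
    out_dir: str | None = None


@dataclass
class SeedResult:
    seed: int
    lambda_star: float
    grid_index: int
    n_active: int
    auc_holdback_mean: float
    auc_test_exact: float
    auc_test_binned: float
    auc_aa_exact: float
    auc_gaussian_pred: float
    chi2_p_controls: float


@dataclass
class RunReport:
    config: RunConfig
    per_seed: list[SeedResult]
    summary: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "per_seed": [asdict(s) for s in self.per_seed],
            "summary": self.summary,
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=float))


def _subseeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _audit_partition(*index_sets: np.ndarray) -> None:
    seen: set[int] = set()
    for s in index_sets:
        ss = set(int(i) for i in s)
        if seen & ss:
            raise RuntimeError("train/holdback/test partition overlaps")
        seen |= ss


def _write_plots(out: Path, seed: int, test_scores, test_labels) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .gaussian import fit_gaussian_summary as _fgs
    from .plots import plot_or_curve, plot_roc, plot_score_histograms

    fig, ax = plt.subplots()
    plot_roc(roc_binned(test_scores, test_labels), ax=ax)
    fig.savefig(out / f"roc_seed{seed}.png", dpi=100)
    plt.close(fig)

    fig, ax = plt.subplots()
    plot_score_histograms(test_scores, test_labels, ax=ax)
    fig.savefig(out / f"score_hist_seed{seed}.png", dpi=100)
    plt.close(fig)

    fig, ax = plt.subplots()
    curve = or_by_percentile(test_scores, test_labels, percentiles=range(0, 97, 4))
    plot_or_curve(curve, _fgs(test_scores, test_labels), ax=ax)
    fig.savefig(out / f"or_curve_seed{seed}.png", dpi=100)
    plt.close(fig)


def _run_one_seed(config: RunConfig, seed: int) -> SeedResult:
    s_geno, s_pheno, s_test, s_design = _subseeds(seed, 4)

    G = simulate_genotypes(
        config.n_samples,
        config.n_variants,
        maf_range=config.maf_range,
        fst=config.fst,
        subpop_fractions=config.subpop_fractions,
        seed=s_geno,
    )
    pheno, _truth = simulate_phenotypes(
        G,
        n_causal=config.n_causal,
        heritability=config.heritability,
        prevalence=config.prevalence,
        sex_effect=config.sex_effect,
        age_effect=config.age_effect,
        seed=s_pheno,
    )

    main_pool = np.flatnonzero(G.subpop_labels == 0)
    aa_pool = np.flatnonzero(G.subpop_labels != 0)

    test_idx = ascertain_case_control(
        pheno, config.n_cases_test, config.n_controls_test, seed=s_test, pool=main_pool
    )
    cv_pool = np.setdiff1d(main_pool, test_idx)
    design = make_cv_design(
        pheno,
        n_folds=config.n_folds,
        n_cases_hold=config.n_cases_hold,
        n_controls_hold=config.n_controls_hold,
        seed=s_design,
        pool=cv_pool,
    )
    _audit_partition(test_idx, *design.holdback_sets, design.training_idx, aa_pool)

    train_idx = design.training_idx
    G_train = G.subset_samples(train_idx)
    pheno_train = pheno.subset(train_idx)
    y_train = transform_regressand(pheno_train, config.regressand)

    screen = MarkerScreen(k=config.top_k).fit(G_train, y_train)
    G_train_sel = screen.transform(G_train)

    path = fit_lambda_path(
        y_train,
        G_train_sel.dosages,
        n_lambdas=config.n_lambdas,
        lambda_min_ratio=config.lambda_min_ratio,
        variant_ids=G_train_sel.variant_ids,
    )

    G_sel = G.subset_variants(screen.selected_ids_)
    auc_by_lambda = evaluate_path_on_folds(path, G_sel, pheno, design)
    per_fold_best = best_lambda_per_fold(path, auc_by_lambda)
    selection = select_lambda_star(per_fold_best)
    gi = choose_grid_index(path, selection.lambda_star)
    model = path.models[gi]

    cov = fit_covariate_model(pheno_train) if config.augment else None

    def score_on(idx: np.ndarray) -> np.ndarray:
        ss = compute_pgs(G_sel.subset_samples(idx), model)
        if cov is not None:
            ss = augment_scores(ss, cov, pheno.subset(idx))
            return ss.augmented
        return ss.pgs

    test_scores = score_on(test_idx)
    test_labels = pheno.status[test_idx]
    aa_scores = score_on(aa_pool)
    aa_labels = pheno.status[aa_pool]

    if np.ptp(test_scores) > 0:
        roc = roc_binned(test_scores, test_labels)
        auc_exact, auc_binned = roc.auc_exact, roc.auc_binned
        summary = fit_gaussian_summary(test_scores, test_labels)
        auc_pred = auc_gaussian(summary)
        chi2_p = chi2_normality(test_scores[test_labels == 0])[2]
    else:
        # uninformative (empty) predictor: every tail metric is chance level
        auc_exact = auc_binned = auc_pred = 0.5
        chi2_p = float("nan")

    if config.out_dir and np.ptp(test_scores) > 0:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_plots(out, seed, test_scores, test_labels)

    return SeedResult(
        seed=seed,
        lambda_star=float(selection.lambda_star),
        grid_index=gi,
        n_active=model.n_active,
        auc_holdback_mean=float(auc_by_lambda[:, gi].mean()),
        auc_test_exact=auc_exact,
        auc_test_binned=auc_binned,
        auc_aa_exact=auc_mann_whitney(aa_scores, aa_labels),
        auc_gaussian_pred=auc_pred,
        chi2_p_controls=chi2_p,
    )


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage for each configured seed and aggregate."""
    if not config.seeds:
        raise ValueError("need at least one seed")
    per_seed = [_run_one_seed(config, s) for s in config.seeds]

    metrics = {
        name: np.array([getattr(r, name) for r in per_seed])
        for name in (
            "auc_holdback_mean",
            "auc_test_exact",
            "auc_test_binned",
            "auc_aa_exact",
            "auc_gaussian_pred",
            "lambda_star",
            "n_active",
        )
    }
    summary = {}
    for name, vals in metrics.items():
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        err = sd
        if name.startswith("auc"):
            err = max(sd, BINNED_AUC_PRECISION)
        summary[name] = {"mean": float(vals.mean()), "sd": sd, "error": err}

    report = RunReport(config=config, per_seed=per_seed, summary=summary)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "report.json")
    return report


def scaling_experiment(
    config: RunConfig, case_counts: list[int]
) -> list[tuple[int, float]]:
    """Mean max-holdback AUC at each training case count, across seeds.

    For each requested case count, training cases are subsampled (all
    training controls kept), the screen and path are refit, and the best
    holdback AUC is recorded; results average over the config's seeds.
    Feed the (n_cases, auc) pairs to :func:`polyrisk.projection.fit_auc_scaling`.
    """
    results = []
    for n_cases in case_counts:
        aucs = []
        for seed in config.seeds:
            aucs.append(_max_holdback_auc_at_case_count(config, seed, n_cases))
        results.append((int(n_cases), float(np.mean(aucs))))
    return results


def _max_holdback_auc_at_case_count(config: RunConfig, seed: int, n_cases: int) -> float:
    s_geno, s_pheno, s_test, s_design = _subseeds(seed, 4)
    G = simulate_genotypes(
        config.n_samples,
        config.n_variants,
        maf_range=config.maf_range,
        fst=config.fst,
        subpop_fractions=config.subpop_fractions,
        seed=s_geno,
    )
    pheno, _ = simulate_phenotypes(
        G,
        n_causal=config.n_causal,
        heritability=config.heritability,
        prevalence=config.prevalence,
        sex_effect=config.sex_effect,
        age_effect=config.age_effect,
        seed=s_pheno,
    )
    main_pool = np.flatnonzero(G.subpop_labels == 0)
    test_idx = ascertain_case_control(
        pheno, config.n_cases_test, config.n_controls_test, seed=s_test, pool=main_pool
    )
    cv_pool = np.setdiff1d(main_pool, test_idx)
    design = make_cv_design(
        pheno,
        n_folds=config.n_folds,
        n_cases_hold=config.n_cases_hold,
        n_controls_hold=config.n_controls_hold,
        seed=s_design,
        pool=cv_pool,
    )
    # subsample training cases to the requested count; keep all controls
    train_idx = design.training_idx
    train_status = pheno.status[train_idx]
    cases = train_idx[train_status == 1]
    controls = train_idx[train_status == 0]
    if n_cases > len(cases):
        raise ValueError(
            f"requested {n_cases} training cases but only {len(cases)} available"
        )
    rng = np.random.default_rng(s_design + 7)
    picked = rng.choice(cases, size=n_cases, replace=False)
    sub_train = np.sort(np.concatenate([picked, controls]))

    G_train = G.subset_samples(sub_train)
    pheno_train = pheno.subset(sub_train)
    y_train = transform_regressand(pheno_train, config.regressand)
    screen = MarkerScreen(k=config.top_k).fit(G_train, y_train)
    path = fit_lambda_path(
        y_train,
        screen.transform(G_train).dosages,
        n_lambdas=config.n_lambdas,
        lambda_min_ratio=config.lambda_min_ratio,
        variant_ids=screen.selected_ids_,
    )
    G_sel = G.subset_variants(screen.selected_ids_)
    sub_design = type(design)(holdback_sets=design.holdback_sets, training_idx=sub_train)
    auc_by_lambda = evaluate_path_on_folds(path, G_sel, pheno, sub_design)
    return float(auc_by_lambda.mean(axis=0).max())
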