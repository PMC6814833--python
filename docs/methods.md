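# Methods

## Scope and shape

`polyrisk` implements a case-control polygenic-prediction workflow as a set
of small estimator classes (`PgsLasso`, `MarkerScreen`, `GaussianRiskModel`,
`AucScaling`) in the scikit-learn idiom, with module-level functions as thin
wrappers, plus a synthetic cohort generator, an orchestration layer
(`run_pipeline`) and a `polyrisk` command-line front end. Everything runs on
synthetic data; no biobank access is assumed or supported.

## Penalized regression

The objective is ½‖y − Xβ‖² + nλ‖β‖₁ with an unpenalized intercept handled
by centering. Note the factor n on the penalty: λ is then a per-sample
penalty, comparable across cohort sizes, and the zero solution is exact for
λ ≥ λ_max = max_j |X_jᵀ(y − ȳ)|/n. The status vector y is regressed
linearly (0/1 coding); for score-overlapping case/control data a linear fit
and a logistic fit rank individuals nearly identically, and ranking is all
AUC and odds-ratio analyses consume. Logistic loss is deliberately out of
scope.

Solver: cyclic coordinate descent with the soft-threshold update, compiled
with numba. Columns are centered and scaled to unit population SD by default
(λ then acts symmetrically across markers); coefficients are mapped back to
the dosage scale on output, so effect files and scoring never depend on the
internal standardization. Convergence is declared when the largest
coefficient change in a sweep falls below `tol` (default 1e-7); the
objective is recorded every sweep and is non-increasing by construction. At
convergence the stationarity conditions hold to ~n·tol in gradient units
(|X_jᵀr| = nλ on the active set, ≤ nλ off it). The λ path has 100 log-spaced
points down to λ_max·1e-3 by default (30 points to λ_max·1e-2 in the
pipeline, where holdback AUC, not objective precision, drives selection) and
warm-starts each fit from the previous solution.

## Marker screening

Each marker is screened by OLS of status on its dosage with intercept; the
two-sided p-value comes from the slope t statistic (n − 2 dof). Screening
uses raw dosages: per-marker rescaling changes slopes but not t statistics,
so the p-value ranking is unaffected. Monomorphic markers are flagged and
excluded from ranking. Ties in p-value break by ascending marker index for
reproducibility. The default keep-count is 50,000 (capped at p), the
conventional GWAS-scale screening width; synthetic runs use k = 500.

## Penalty selection

Five disjoint holdback sets, stratified to exact case/control counts, are
drawn before training; the training set is the remainder. Every path model
is scored on every holdback by exact Mann-Whitney AUC. λ* = mean + 1 SD of
the per-fold best-AUC λs, the shift pointing toward more penalization
(sparser models). The mean is taken on the linear λ scale by default; a
log10-scale variant is provided (`scale="log"`) because the grid is
log-spaced and either reading of "average" is defensible. When λ* lands
between grid points the nearest grid λ at or above is used, again erring
sparse. Holdback size defaults to 1000 + 1000 per fold at biobank scale and
is scaled down proportionally (150 + 150) in the synthetic pipeline.

## Scoring and covariates

PGS_i = Σ_j X_ij β*_j + intercept on the dosage scale. Because SNP state,
sex and age are treated as independent degrees of freedom, a linear model of
status on (1, sex, age) — fit on training samples only, then frozen — can be
added directly to the genetic score ("augmented" score). Three training
regressands are supported: raw status; status minus the covariate fit
(modification 1, age in years unstandardized); and status standardized to
zero mean/unit SD within each sex followed by removal of a fresh age
regression (modification 2).

## Empirical metrics

- Exact AUC: Mann-Whitney from average ranks; ties count ½.
- Binned AUC: equal-width score bins spanning [min, max] (default 100),
  cumulative tail counts, trapezoidal integration. At default binning it
  tracks the exact AUC to about 0.01; the test suite verifies both the
  bound and convergence under bin refinement.
- OR-by-percentile: at each percentile cutpoint z of the pooled score
  distribution (a controls-only reference is available), OR(z) compares
  tail case/control odds to population odds. CIs treat the two tail counts
  as Poisson: SE² = 1/n₁ + 1/n₀ on log OR. Cutpoints with an empty tail are
  flagged, not dropped.

## Displaced-Gaussian analytics

Stratum means/SDs (sample SD, n − 1) define the Gaussian summary; the
analytic AUC, tail OR, mixture density, BOR and absolute-risk translation
are the closed forms given in the README. Tail probabilities are computed
with the complementary CDF directly, so OR(z) remains stable far into the
tail where 1 − Φ would cancel. Normality is checked by a χ² test with
Sturges' rule for the bin count (⌈1 + log₂ n⌉); bins are equal-probability
under the fitted normal — Sturges fixes only the count, and equal-probability
placement keeps expected counts valid and power reasonable — with
dof = bins − 3 for the two fitted parameters.

## Synthetic cohorts

The generator produces the structure the analysis assumes, not a realistic
genome:

- Ancestral allele frequencies uniform on (0.05, 0.5); per-subpopulation
  frequencies Balding-Nichols Beta(p(1−F)/F, (1−p)(1−F)/F) with divergence
  F = Fst, the simplest one-parameter model of an "adjacent ancestry" test
  group; dosages Binomial(2, f). An optional flag adds uniform jitter to
  mimic imputed dosages.
- Phenotypes from a liability threshold: a uniformly chosen causal subset
  gets i.i.d. normal effects on the standardized-genotype scale, rescaled so
  the realized genetic variance equals h² exactly; liability adds optional
  sex and standardized-age effects and N(0, 1 − h²) noise; cases are the top
  realized-prevalence quantile, so even small cohorts hit the requested
  prevalence to integer rounding. Ages are uniform on 40–70, a biobank-like
  span.

Not emulated: linkage disequilibrium (the penalized fit therefore never
faces correlated predictors), genotyping error, variant-frequency/effect
coupling, and any non-additive architecture. Passing pipeline tests
demonstrate correct mechanics and statistical calibration under this
idealized architecture, not expected performance on real genomes, where LD
and confounding make prediction harder.

Default study conditions for the pipeline tests: n = 20,000 samples
(85% training ancestry, 15% adjacent ancestry at Fst = 0.01), p = 2,000
markers, 50 causals, h² = 0.5, prevalence 0.12, five seeds; five holdback
sets of 150 + 150 and a 300 + 300 same-ancestry test set. These sizes keep a
full five-seed run at a few minutes on one core while leaving the holdback
and test AUCs well-resolved (binomial SE ≲ 0.02).

## Scaling and cost-benefit

`fit_auc_scaling` is OLS of AUC on log(N/1000) (natural log internally;
predictions are base-invariant, which is tested). Presentation-grade
extrapolations truncate — not round — to two decimals: the three published
50k-case extrapolations are consistent with flooring the OLS values and one
of them is inconsistent with rounding, so truncation is the documented
convention, with the full-precision value always available. The cost-benefit
calculator evaluates X = Σ T_i(F_i B_i − C_i) − G, flooring negative
condition terms at zero (a screening program simply opts out of conditions
that do not pay).

## Numerical and degenerate-input conventions

- Zero-variance (monomorphic) markers: flagged, slope 0, p = 1, excluded
  from ranking; the solver skips zero-norm columns.
- Constant scores (empty model): AUC defined as 0.5 via the tie convention;
  the pipeline reports chance-level metrics and skips the Gaussian fit.
- Gaussian summaries require ≥ 2 observations and positive SD per stratum.
- All randomness flows through `numpy.random.default_rng` seeds; a run's
  report is byte-identical across repeats with the same config.

## Known limitations

No LD model and no covariate-adjusted screening; λ* selection assumes the
holdback AUC curve is unimodal-ish (it snaps to one grid point); the
adjacent-ancestry comparison uses a single Fst parameter and so cannot
reproduce the gradual performance fall-off seen across real ancestry
distances; absolute-risk translation inherits the displaced-normal
assumption and degrades in the extreme tails if scores are non-Gaussian.
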