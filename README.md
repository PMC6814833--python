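# polyrisk

Sparse polygenic risk scores for case-control cohorts, with a
displaced-Gaussian risk calculus.

`polyrisk` is for statistical geneticists and methodologists who want a
compact, fully testable implementation of the classic biobank-scale
polygenic-prediction workflow: L1-penalized (LASSO) training of a
case-control predictor on a genotype dosage matrix, penalty selection on
disjoint holdback sets, and downstream risk analytics built on the empirical
observation that case and control score distributions are approximately two
displaced normal distributions. A synthetic two-ancestry cohort generator
with a liability-threshold architecture stands in for real biobank data, so
the entire pipeline runs on a laptop with no data access agreements.

## The model

Training minimizes the penalized least-squares objective over effect sizes
β for p markers and n individuals with status y ∈ {0, 1}:

    O_λ(β) = ½‖y − Xβ‖² + nλ‖β‖₁,   β* = argmin O_λ(β)

by cyclic coordinate descent with warm starts along a decreasing log-spaced
λ grid. Markers enter the fit after single-marker screening (top-k by
p-value). The polygenic score of individual i is PGS_i = Σ_j X_ij β*_j. The
selected penalty λ* is the per-holdback-fold best-AUC λ, averaged across the
five folds, shifted one standard deviation toward more penalization.

With case scores ~ N(μ₁, σ₁²) and controls ~ N(μ₀, σ₀²):

- analytic AUC: Φ((μ₁ − μ₀) / √(σ₁² + σ₀²))
- tail odds ratio: OR(z) = Φ̄((z − μ₁)/σ₁) / Φ̄((z − μ₀)/σ₀)
- binned odds ratio BOR(z) = f₁(z)/f₀(z), independent of a sub-population's
  case/control ratio r, giving absolute risk P(case|z) = 1/(1 + 1/(r·BOR))
  in any population with known prevalence
- AUC grows roughly linearly in log N over training-set sizes; an OLS fit of
  AUC on log(N/1000) extrapolates to future cohort sizes.

## Worked example

```python
from polyrisk import RunConfig, run_pipeline

config = RunConfig(seeds=(0, 1, 2))   # 20k samples, 2k SNPs, 50 causals, h2=0.5
report = run_pipeline(config)
for name in ("auc_holdback_mean", "auc_test_exact", "auc_aa_exact",
             "auc_gaussian_pred"):
    s = report.summary[name]
    print(f"{name}: {s['mean']:.3f} ({s['error']:.3f})")
```

prints

```
auc_holdback_mean: 0.844 (0.012)
auc_test_exact: 0.850 (0.032)
auc_aa_exact: 0.843 (0.010)
auc_gaussian_pred: 0.850 (0.027)
```

Reading: the penalty chosen on the holdback sets gives a predictor whose
AUC on a never-touched same-ancestry test set is ~0.85; performance on the
drifted "adjacent ancestry" subpopulation (Fst = 0.01) is essentially the
same; and the closed-form AUC implied by the fitted case/control Gaussian
summaries agrees with the empirical rank-based AUC to about 0.01 — the
displaced-normal approximation at work. Parenthesized errors are the larger
of the across-seed SD and the 0.01 binned-integration precision.

The same stages are available from the shell:

```bash
polyrisk simulate --n 2000 --p 500 --n-causal 25 --h2 0.5 --prevalence 0.12 \
    --seed 1 --out-prefix cohort
polyrisk screen --genotypes cohort.raw --phenotypes cohort.pheno.csv \
    --top-k 200 --out stats.csv
polyrisk train --genotypes cohort.raw --phenotypes cohort.pheno.csv \
    --variants stats.csv --n-lambdas 30 --out models/
```

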