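"""Synthetic case-control cohorts with a liability-threshold genetic architecture.

The generator emulates the statistical structure a polygenic-risk analysis
assumes about a biobank cohort: a sparse additive genetic liability with a
chosen heritability, a prevalence-determined case threshold, sex and age
effects on the liability, and an "adjacent ancestry" subpopulation whose
allele frequencies have drifted from the training population (Balding-Nichols
divergence parameterized by Fst).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "TrueModel",
    "simulate_genotypes",
    "simulate_phenotypes",
    "ascertain_case_control",
]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with per-variant metadata.

    Dosages count effect alleles, so each entry lies in [0, 2]; fractional
    values mimic imputed genotypes. ``subpop_labels`` records which
    subpopulation each sample was drawn from (0 = training ancestry).
    """

    sample_ids: list[str]
    variant_ids: list[str]
    dosages: np.ndarray  # (n, p), float64 in [0, 2]
    allele_freqs: np.ndarray  # (p,) effect-allele frequency in ancestral pop
    chromosome_labels: list[str]
    subpop_labels: np.ndarray = field(default=None)  # (n,) int
    subpop_allele_freqs: np.ndarray | None = None  # (n_subpops, p) latent freqs

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
        n, p = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.variant_ids) != p or len(self.chromosome_labels) != p:
            raise ValueError("variant metadata length does not match dosage columns")
        if not np.all(np.isfinite(self.dosages)):
            raise ValueError("dosages contain non-finite values")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        if self.subpop_labels is None:
            self.subpop_labels = np.zeros(n, dtype=int)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def subset_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            variant_ids=list(self.variant_ids),
            dosages=self.dosages[idx],
            allele_freqs=self.allele_freqs,
            chromosome_labels=list(self.chromosome_labels),
            subpop_labels=self.subpop_labels[idx],
            subpop_allele_freqs=self.subpop_allele_freqs,
        )

    def subset_variants(self, variant_ids: list[str]) -> "GenotypeMatrix":
        pos = {v: j for j, v in enumerate(self.variant_ids)}
        cols = [pos[v] for v in variant_ids]
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variant_ids=list(variant_ids),
            dosages=self.dosages[:, cols],
            allele_freqs=self.allele_freqs[cols],
            chromosome_labels=[self.chromosome_labels[j] for j in cols],
            subpop_labels=self.subpop_labels,
            subpop_allele_freqs=None
            if self.subpop_allele_freqs is None
            else self.subpop_allele_freqs[:, cols],
        )


@dataclass
class PhenotypeTable:
    """Per-sample case/control status with sex and age covariates."""

    sample_ids: list[str]
    status: np.ndarray  # (n,) in {0, 1}
    sex: np.ndarray  # (n,) in {0, 1}
    age: np.ndarray  # (n,) years, > 0

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=int)
        self.sex = np.asarray(self.sex, dtype=int)
        self.age = np.asarray(self.age, dtype=float)
        n = len(self.sample_ids)
        if not (len(self.status) == len(self.sex) == len(self.age) == n):
            raise ValueError("phenotype columns must all have one entry per sample")
        if not np.isin(self.status, (0, 1)).all():
            raise ValueError("status must be 0/1")
        if np.any(self.age <= 0):
            raise ValueError("age must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, idx: np.ndarray) -> "PhenotypeTable":
        idx = np.asarray(idx)
        return PhenotypeTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            status=self.status[idx],
            sex=self.sex[idx],
            age=self.age[idx],
        )


@dataclass
class TrueModel:
    """The generative architecture behind a simulated phenotype."""

    causal_variant_ids: list[str]
    causal_effects: np.ndarray  # on the standardized-genotype scale
    heritability_target: float
    prevalence: float
    sex_effect: float
    age_effect: float
    liability_threshold: float


def simulate_genotypes(
    n_samples: int,
    n_variants: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    fst: float = 0.0,
    subpop_fractions: tuple[float, ...] = (1.0,),
    seed: int = 0,
    fractional_dosages: bool = False,
) -> GenotypeMatrix:
    """Draw biallelic dosages for one or more diverged subpopulations.

    Ancestral effect-allele frequencies are uniform on ``maf_range``. Each
    subpopulation's frequencies are drawn from the Balding-Nichols beta
    distribution Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral frequency
    p with divergence ``fst``; ``fst = 0`` leaves them identical. Dosages are
    Binomial(2, freq) per sample; ``fractional_dosages`` adds uniform jitter
    (clipped to [0, 2]) to mimic imputed rather than directly called
    genotypes.
    """
    if n_samples < 2 or n_variants < 1:
        raise ValueError("need n_samples >= 2 and n_variants >= 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5] with lo <= hi")
    if fst < 0:
        raise ValueError("fst must be >= 0")
    fractions = np.asarray(subpop_fractions, dtype=float)
    if fractions.size == 0 or np.any(fractions < 0) or abs(fractions.sum() - 1) > 1e-9:
        raise ValueError("subpop_fractions must be nonnegative and sum to 1")

    rng = np.random.default_rng(seed)
    ancestral = rng.uniform(lo, hi, size=n_variants)

    # integer subpopulation sizes; remainder goes to the first subpopulation
    sizes = np.floor(fractions * n_samples).astype(int)
    sizes[0] += n_samples - sizes.sum()

    dosage_blocks = []
    labels = []
    subpop_freqs = np.empty((len(sizes), n_variants))
    for k, nk in enumerate(sizes):
        if fst == 0:
            freqs_k = ancestral
        else:
            a = ancestral * (1 - fst) / fst
            b = (1 - ancestral) * (1 - fst) / fst
            freqs_k = rng.beta(a, b)
            # guard against numerically degenerate draws
            freqs_k = np.clip(freqs_k, 1e-6, 1 - 1e-6)
        subpop_freqs[k] = freqs_k
        block = rng.binomial(2, freqs_k, size=(nk, n_variants)).astype(float)
        if fractional_dosages:
            block = np.clip(block + rng.uniform(-0.3, 0.3, size=block.shape), 0.0, 2.0)
        dosage_blocks.append(block)
        labels.append(np.full(nk, k, dtype=int))

    dosages = np.vstack(dosage_blocks)
    return GenotypeMatrix(
        sample_ids=[f"S{i:06d}" for i in range(n_samples)],
        variant_ids=[f"rs{j:06d}" for j in range(n_variants)],
        dosages=dosages,
        allele_freqs=ancestral,
        chromosome_labels=[str(1 + j % 22) for j in range(n_variants)],
        subpop_labels=np.concatenate(labels),
        subpop_allele_freqs=subpop_freqs,
    )


def simulate_phenotypes(
    G: GenotypeMatrix,
    n_causal: int,
    heritability: float,
    prevalence: float,
    sex_effect: float = 0.0,
    age_effect: float = 0.0,
    age_range: tuple[float, float] = (40.0, 70.0),
    seed: int = 0,
) -> tuple[PhenotypeTable, TrueModel]:
    """Assign case/control status from a thresholded additive liability.

    ``n_causal`` variants are chosen uniformly at random; their effects are
    i.i.d. normal on the standardized-genotype scale, rescaled so the realized
    genetic component has variance exactly ``heritability``. The liability is
    genetic + sex_effect*sex + age_effect*standardized(age) + environmental
    noise of variance 1 - heritability, and a sample is a case iff its
    liability exceeds the realized (1 - prevalence) quantile, so small cohorts
    hit the requested prevalence up to integer rounding.
    """
    n, p = G.dosages.shape
    if not 0 < n_causal <= p:
        raise ValueError("n_causal must be in [1, n_variants]")
    if not 0 < heritability < 1:
        raise ValueError("heritability must lie in (0, 1)")
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie in (0, 1)")

    rng = np.random.default_rng(seed)
    causal_idx = np.sort(rng.choice(p, size=n_causal, replace=False))
    effects = rng.standard_normal(n_causal)

    X = G.dosages[:, causal_idx]
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    g = Z @ effects
    g_sd = g.std()
    if g_sd > 0:
        scale = np.sqrt(heritability) / g_sd
    else:  # pragma: no cover - all-monomorphic causal draw
        scale = 0.0
    g *= scale
    effects = effects * scale

    sex = rng.integers(0, 2, size=n)
    age = rng.uniform(age_range[0], age_range[1], size=n)
    age_std = (age - age.mean()) / age.std()

    noise = rng.standard_normal(n) * np.sqrt(1 - heritability)
    liability = g + sex_effect * sex + age_effect * age_std + noise
    threshold = np.quantile(liability, 1 - prevalence)
    status = (liability > threshold).astype(int)

    pheno = PhenotypeTable(
        sample_ids=list(G.sample_ids), status=status, sex=sex, age=age
    )
    truth = TrueModel(
        causal_variant_ids=[G.variant_ids[j] for j in causal_idx],
        causal_effects=effects,
        heritability_target=heritability,
        prevalence=prevalence,
        sex_effect=sex_effect,
        age_effect=age_effect,
        liability_threshold=float(threshold),
    )
    return pheno, truth


def ascertain_case_control(
    pheno: PhenotypeTable,
    n_cases: int,
    n_controls: int,
    seed: int = 0,
    pool: np.ndarray | None = None,
) -> np.ndarray:
    """Sample a case/control index set uniformly within each status stratum.

    ``pool`` restricts sampling to the given sample indices (pass the
    complement of previously drawn sets to build disjoint designs). Raises if
    a stratum cannot supply the requested count, naming the deficit.
    """
    rng = np.random.default_rng(seed)
    pool = np.arange(pheno.n_samples) if pool is None else np.asarray(pool)
    status = pheno.status[pool]
    case_pool = pool[status == 1]
    control_pool = pool[status == 0]
    if len(case_pool) < n_cases:
        raise ValueError(
            f"requested {n_cases} cases but only {len(case_pool)} available "
            f"(deficit {n_cases - len(case_pool)})"
        )
    if len(control_pool) < n_controls:
        raise ValueError(
            f"requested {n_controls} controls but only {len(control_pool)} "
            f"available (deficit {n_controls - len(control_pool)})"
        )
    chosen_cases = rng.choice(case_pool, size=n_cases, replace=False)
    chosen_controls = rng.choice(control_pool, size=n_controls, replace=False)
    return np.sort(np.concatenate([chosen_cases, chosen_controls]))
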