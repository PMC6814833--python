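import numpy as np
import pytest

from polyrisk import simulate_genotypes, simulate_phenotypes


@pytest.fixture(scope="session")
def planted_cohort():
    """20k-sample cohort with 50 planted causals at h2=0.5, prevalence 0.12."""
    G = simulate_genotypes(20_000, 1_000, seed=11)
    pheno, truth = simulate_phenotypes(
        G, n_causal=50, heritability=0.5, prevalence=0.12, seed=12
    )
    return G, pheno, truth


@pytest.fixture(scope="session")
def small_cohort():
    """2k-sample cohort cheap enough for per-test reuse."""
    G = simulate_genotypes(2_000, 100, seed=21)
    pheno, truth = simulate_phenotypes(
        G, n_causal=10, heritability=0.5, prevalence=0.2, seed=22
    )
    return G, pheno, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
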