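import numpy as np
import pytest

import famhist as fh


@pytest.fixture(scope="session")
def nuclear_cohort():
    return fh.generate_cohort(200, 200, seed=101)


@pytest.fixture(scope="session")
def three_gen_cohort():
    return fh.generate_three_generation_cohort(200, 200, seed=102)


@pytest.fixture(scope="session")
def causal_sim(nuclear_cohort):
    """One simulated case-control replicate under the causal model."""
    genotypes = fh.simulate_genotypes(nuclear_cohort, fh.DEFAULT_MAFS, seed=103)
    config = fh.PhenotypeModelConfig(model="causal_model")
    phenos = fh.simulate_case_control(nuclear_cohort, genotypes, config, seed=104)
    return genotypes, phenos, config


@pytest.fixture(scope="session")
def posterior_table():
    """Posterior liability table at a reduced (but stable) Monte-Carlo size."""
    return fh.build_posterior_table(
        fh.LTFHConfig(h2=0.28, prevalence=0.3, n_mc=400_000, seed=7), max_siblings=2
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
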