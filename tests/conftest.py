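import numpy as np
import pytest

from trastools.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A fast desk-scale cohort with the full planted architecture."""
    return simulate_cohort(SimulationConfig(
        n_samples=40, n_snps=60, n_transcripts=40, seed=11))


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the full study conditions (102 accessions,
    2000 SNPs, 1000 transcripts)."""
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_pipeline(default_cohort):
    from trastools.pipeline import run_pipeline_data

    co = default_cohort
    return run_pipeline_data(co.genotypes, co.expression, co.phenotypes,
                             co.modules, co.go_annotation)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
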