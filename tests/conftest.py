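import pytest

from syndriver import synthetic_data


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down cohort for fast unit tests."""
    return synthetic_data.CohortConfig(
        n_genes=60,
        n_cancer_genes=12,
        cds_length_range=(90, 1200),
        n_patients=80,
        n_germline=200,
        n_somatic_normal=150,
        n_somatic_cancer=400,
        n_putative_driver=120,
        n_missense=300,
        n_planted_drivers=12,
        n_burden_boost_genes=4,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return synthetic_data.generate_cohort(small_config, seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the default study conditions."""
    return synthetic_data.generate_cohort(seed=7)
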