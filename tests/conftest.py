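"""Shared cohort fixtures (generated in-memory; nothing on disk)."""
import pytest

from redoxmap.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort at the emulated study design (3000 sites)."""
    return generate_cohort(CohortConfig(seed=5))


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort for fast structural tests."""
    return generate_cohort(CohortConfig(seed=11, n_sites=400, n_proteins=150,
                                        n_metabolites=60))


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free cohort: no reporter noise, no dropout, no channel loading."""
    return generate_cohort(CohortConfig(seed=12, n_sites=300, n_proteins=100,
                                        noise_cv=0.0, dropout_midpoint=None,
                                        channel_load_range=(1.0, 1.0)))


@pytest.fixture(scope="session")
def group_order():
    return ["young", "middle", "old"]
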