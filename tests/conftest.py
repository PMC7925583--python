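import pytest
from hypothesis import HealthCheck, settings

from hospitalome.synthetic import SimConfig, generate_cohort

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """A small noisy cohort with ground truth, shared across tests."""
    return generate_cohort(SimConfig(n_patients=12, seed=7))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Noiseless, exactly observed cohort: the forward model is invertible."""
    return generate_cohort(SimConfig.noiseless(n_patients=50, n_taxa=10, n_drug_groups=4, seed=1))
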