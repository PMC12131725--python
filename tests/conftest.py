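import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from neovanc import (
    CohortConfig,
    CompiledDataset,
    final_model_parameters,
    final_model_spec,
    fit_model,
    simulate_cohort,
)

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def final_spec():
    return final_model_spec()


@pytest.fixture(scope="session")
def final_params():
    return final_model_parameters()


@pytest.fixture(scope="session")
def cohort60(final_spec, final_params):
    """A 60-subject virtual cohort simulated from the reference model."""
    return simulate_cohort(CohortConfig(n=60), final_params, final_spec, seed=5)


@pytest.fixture(scope="session")
def data60(cohort60, final_spec):
    return CompiledDataset(cohort60, final_spec)


@pytest.fixture(scope="session")
def fit60(data60, final_spec):
    """FOCE fit of the reference model structure to the 60-subject cohort."""
    fit = fit_model(data60, final_spec, seed=5)
    assert fit.converged
    return fit
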