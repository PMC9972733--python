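import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from epimediate.cohort import CohortConfig, generate_cohort, null_config

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_null_cohort():
    """Null cohort used by several suites (no planted effects, no direct effect)."""
    cohort, truth = generate_cohort(null_config(n_samples=200, n_sites=300, n_genes=30, seed=11))
    return cohort, truth


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with three strong, well-separated planted mediators."""
    cfg = CohortConfig(
        n_samples=400, n_sites=500, n_genes=50, n_planted=3,
        alpha_effects=0.008, beta_effects=-40.0, direct_effect=-0.02, seed=21,
    )
    cohort, truth = generate_cohort(cfg)
    return cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
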