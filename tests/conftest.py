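import numpy as np
import pytest

from lymphgraph.synthetic import CohortSpec, generate_feature_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small separable cohort reused across tests (read-only)."""
    spec = CohortSpec(
        n_patients=120,
        prevalence=0.4,
        n_features=30,
        n_informative=5,
        n_redundant=5,
        class_separation=2.0,
        seed=7,
    )
    return generate_feature_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
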