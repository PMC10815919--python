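import numpy as np
import pytest

from hlos import CohortSpec, default_spec, generate_cohort


@pytest.fixture(scope="session")
def small_realistic():
    """One seeded realistic cohort, small enough for fast unit tests."""
    spec = default_spec(n_patients=600, seed=42)
    table, _ = generate_cohort(spec)
    return spec, table


@pytest.fixture(scope="session")
def small_faithful():
    """Model-faithful cohort with known ground truth."""
    spec = CohortSpec(n_patients=500, mode="model_faithful", seed=7, n_features=4)
    table, truth = generate_cohort(spec)
    return table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
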