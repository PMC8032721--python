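import numpy as np
import pytest

from lesionmgmt.cohort import GeneratorConfig, generate_exact_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration cohort shared by read-only tests."""
    return generate_exact_cohort(GeneratorConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
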