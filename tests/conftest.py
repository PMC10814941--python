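import numpy as np
import pytest

from dermafuse import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small in-memory cohort: 3 classes x 3 tumors, 4 observations each."""
    spec = syn.CohortSpec(
        tumors_per_class={"superficial_bcc": 3, "nodular_bcc": 3, "benign": 3},
        observations_per_tumor=4,
        seed=7,
    )
    return syn.simulate_modalities(spec, "well-separated")
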