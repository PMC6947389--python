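import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gwgtraj as g

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort at reduced size, shared across tests."""
    cfg = g.default_config(n_subjects=1500, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return g.generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
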