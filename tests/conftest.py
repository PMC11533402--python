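import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def clean_field():
    """A noise-free synthetic field with full marker coverage (50/20/10)."""
    import gliaphen as gp

    params = gp.FieldSimParams(seed=7, noise_sd=0.0, marker_overlap_target=1.0)
    dapi, glia, phen, truth = gp.generate_field(params)
    return params, dapi, glia, phen, truth
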