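import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20230123)


@pytest.fixture
def blink_mixture():
    """One standard contaminated segment (p = 1) with its ground truth."""
    from cissadwt.synthetic import BlinkParams, gen_eeg, gen_eog, mix

    q = gen_eeg(2500, 250.0, seed=11)
    k = gen_eog(2500, 250.0, BlinkParams(seed=12))
    return mix(q, k, 1.0)
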