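import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def std_normal_prior():
    from genbayes import BeliefState
    return BeliefState.gaussian(0.0, 1.0)


@pytest.fixture
def small_survival():
    """n=60, p=3 genotype survival data with one strong effect."""
    from genbayes import gen_survival
    ds, truth = gen_survival(60, 3, maf=0.3, beta_true={0: 0.9},
                             censor_rate=0.2, seed=11)
    return ds, truth
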