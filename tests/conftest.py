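import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_censored_data(seed, n=None, n_causes=2, event_scale=2.0, censor_scale=3.0):
    """Random censored competing-risks dataset: (observed_time, cause)."""
    r = np.random.default_rng(seed)
    if n is None:
        n = int(r.integers(5, 50))
    t = r.exponential(event_scale, n)
    c = r.exponential(censor_scale, n)
    obs = np.minimum(t, c)
    cause = np.where(t <= c, r.integers(1, n_causes + 1, n), 0)
    return obs, cause


@pytest.fixture
def censored_data_factory():
    return make_censored_data
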