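import numpy as np
import pytest
from hypothesis import settings

from snvsig.genotype import SurvivalData

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_surv(time, event):
    time = np.asarray(time, dtype=float)
    return SurvivalData(time, np.asarray(event), [f"S{i}" for i in range(len(time))])


@pytest.fixture
def censored_surv(rng):
    """Moderately censored survival data driven by a known linear predictor."""
    n = 80
    x = rng.standard_normal(n)
    t = rng.exponential(1.0, n) * np.exp(-0.8 * x)
    c = rng.exponential(2.0, n)
    return make_surv(np.minimum(t, c), (t <= c).astype(int)), x
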