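import numpy as np
import pytest
from hypothesis import settings

from histoclock import SimulationConfig, generate
from histoclock.clock import logo_cv_train
from histoclock.signal import log2_background_subtract, quantify_density

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def rng(seed=0):
    return np.random.default_rng(seed)


@pytest.fixture(scope="session")
def small_sim():
    """A small Poisson-count simulation exercising the full input surface."""
    return generate(SimulationConfig(n_peaks=200, n_samples=30, seed=11))


@pytest.fixture(scope="session")
def clock_regime():
    """The standard clock-recovery regime: 2,000 peaks x 100 samples, 5%
    informative linear peaks over ages 5-75, trained once per session."""
    cfg = SimulationConfig(
        n_peaks=2000, n_samples=100, fraction_linear=0.05,
        age_range=(5.0, 75.0), seed=7,
    )
    res = generate(cfg)
    mat = log2_background_subtract(quantify_density(res.matrix))
    model, cv = logo_cv_train(
        mat, alpha_grid=[0.1, 0.5, 1.0], n_lambda=20, n_groups=11
    )
    return res, mat, model, cv
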