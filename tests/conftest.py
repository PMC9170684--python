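import numpy as np
import pytest

from vistreams import synthetic


@pytest.fixture(scope="session")
def small_population():
    cfg = synthetic.smoke_config(n_mice=2, n_per_area_mouse=30)
    return synthetic.sample_population(cfg, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_population):
    """2 mice x 2 areas x 30 neurons, all three batteries, default noise."""
    return synthetic.simulate_trial_traces(small_population,
                                           datasets=(1, 2, 3), seed=12)


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free simulation of dataset 1 for exactness checks."""
    cfg = synthetic.smoke_config(n_mice=1, n_per_area_mouse=8,
                                 areas=("V1",), noise_sigma=0.0,
                                 gain_cv=0.0)
    pop = synthetic.sample_population(cfg, seed=21)
    return synthetic.simulate_trial_traces(pop, datasets=(1,), seed=22)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
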