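import numpy as np
import pytest

from sasskit.sass import sass_fit
from sasskit.spectral import BandSpec
from sasskit.synth import SynthConfig, generate_session

BAND = BandSpec(10.0, 1.0)


@pytest.fixture(scope="session")
def default_pair():
    """The default-condition session pair: 200 trials, default seed."""
    cfg = SynthConfig()
    rec0, tr0 = generate_session(cfg, with_stim=False)
    rec1, tr1 = generate_session(cfg, with_stim=True)
    return cfg, (rec0, tr0), (rec1, tr1)


@pytest.fixture(scope="session")
def default_model(default_pair):
    cfg, (rec0, _), (rec1, _) = default_pair
    return sass_fit(rec0, rec1, BAND)


@pytest.fixture(scope="session")
def quick_pair():
    """A small session pair for unit tests (40 trials)."""
    cfg = SynthConfig(n_trials=40, seed=11)
    rec0, tr0 = generate_session(cfg, with_stim=False)
    rec1, tr1 = generate_session(cfg, with_stim=True)
    return cfg, (rec0, tr0), (rec1, tr1)


@pytest.fixture(scope="session")
def quick_model(quick_pair):
    cfg, (rec0, _), (rec1, _) = quick_pair
    return sass_fit(rec0, rec1, BAND)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
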