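import numpy as np
import pytest

import fixsearch as fx


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic session shared across test modules.

    Small feature dimension and unit counts keep it fast; planted effects
    are at their defaults (axis coding, attention gain, theta locking).
    """
    cfg = fx.SyntheticConfig(
        n_trials=80,
        n_stimuli_per_category=10,
        n_features=64,
        n_units_per_area={"V4": 4, "TE": 4},
        n_channels_per_area=2,
    )
    stimuli = fx.generate_stimulus_features(
        cfg.n_stimuli_per_category, cfg.n_features, cfg.separation, seed=11
    )
    truth = fx.generate_unit_population(cfg, stimuli, seed=12)
    session = fx.generate_session(cfg, stimuli, truth, seed=13)
    return cfg, stimuli, truth, session


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
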