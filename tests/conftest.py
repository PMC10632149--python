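import numpy as np
import pytest

from synckit import synth


@pytest.fixture(scope="session")
def fixtures():
    """Deterministic worked fixtures with closed-form expected values."""
    return synth.generate_worked_fixtures()


@pytest.fixture(scope="session")
def small_session():
    """A compact synthetic session: one 20-Hz laser, few units/components."""
    cfg = synth.GeneratorConfig(
        duration=150.0, seed=11, laser_plan=((20, 60.0, 30.0),),
        regions={"SSp": 4, "PVZ": 2}, n_components=6, latent_dim=2)
    session, truth = synth.generate_session(cfg)
    return cfg, session, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
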