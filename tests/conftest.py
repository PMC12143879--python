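import numpy as np
import pytest

from dualpop.synthetic_data import (
    InactivationSpec,
    SynthConfig,
    generate_inactivation_dataset,
    generate_session,
)


@pytest.fixture(scope="session")
def small_session():
    """A small control session reused by read-only tests."""
    cfg = SynthConfig(n_units_per_region=12, n_trials=24, seed=11)
    bundle, truth = generate_session(cfg)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def light_session():
    cfg = SynthConfig(
        n_units_per_region=15,
        n_trials=60,
        inactivation=InactivationSpec("A", 0.8, 0.4, 10.0),
        seed=21,
    )
    bundle, truth = generate_inactivation_dataset(cfg)
    return cfg, bundle, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
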