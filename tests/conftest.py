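import numpy as np
import pytest

from plnet import ArchConfig, FixtureSpec, build_plnet, generate


@pytest.fixture
def tiny_config():
    """Depth-3, narrow model on 32x32 inputs — fast enough for unit tests."""
    return ArchConfig(
        ocs=1.0,
        n_steps=2,
        n_stages=2,
        base_channels=(4, 8, 16),
        in_channels=3,
        n_classes=1,
        input_size=32,
    )


@pytest.fixture
def tiny_model(tiny_config):
    return build_plnet(tiny_config, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def lesion_samples():
    return generate(FixtureSpec(kind="lesion", size=64, n_samples=8, seed=7))


@pytest.fixture(scope="session")
def ring_samples():
    return generate(FixtureSpec(kind="ring", size=64, n_samples=50, seed=3))
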