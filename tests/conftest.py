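import dataclasses

import numpy as np
import pytest

from dsaseg import (AttentionConfig, NetworkConfig, PhantomSpec, build_model,
                    generate_phantom)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_net_cfg():
    return NetworkConfig(in_channels=2, first_filters=2)


@pytest.fixture(scope="session")
def tiny_attn_cfg():
    return AttentionConfig(heads=1, proj_dim=8, modules_per_pathway=1)


@pytest.fixture(scope="session")
def tiny_model(tiny_net_cfg, tiny_attn_cfg):
    """A very thin network bound to 32^3 patches, shared across tests."""
    return build_model(tiny_net_cfg, tiny_attn_cfg, patch_size=(32, 32, 32),
                       variant="dsa", seed=7)


@pytest.fixture(scope="session")
def small_phantom():
    """One 32^3 two-channel phantom with a lesion, plus its mask."""
    spec = PhantomSpec(shape=(32, 32, 32), seed=11)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def phantom_batch():
    """Four seeded 32^3 phantoms (volume, mask) pairs."""
    spec = PhantomSpec(shape=(32, 32, 32))
    return [generate_phantom(dataclasses.replace(spec, seed=s)) for s in range(4)]
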