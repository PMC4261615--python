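import dataclasses

import numpy as np
import pytest

from octfractal import PhantomSpec, generate_bscan
from octfractal.layers import LAYERS


def small_spec(**overrides) -> PhantomSpec:
    """Desk-scale phantom: full layer stack, reduced lateral/depth extent."""
    defaults = dict(n_ascans=128, n_depth=256, seed=0)
    defaults.update(overrides)
    return PhantomSpec(**defaults)


def with_beta(spec: PhantomSpec, layer: str, beta: float) -> PhantomSpec:
    betas = list(spec.layer_beta)
    betas[LAYERS.index(layer)] = beta
    return dataclasses.replace(spec, layer_beta=tuple(betas))


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, shadow-free phantom with default layer parameters."""
    spec = small_spec(speckle_looks=None, texture_amplitude=0.0)
    return generate_bscan(spec)


@pytest.fixture(scope="session")
def default_phantom():
    """Default-noise phantom with two planted vessel shadows."""
    spec = small_spec(seed=11, shadow_columns=((40, 6), (90, 4)))
    return spec, generate_bscan(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
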