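import numpy as np
import pytest

from kronsdr import (
    BinarySimConfig,
    ContinuousSimConfig,
    MatrixDataset,
    build_fourier,
    generate_binary,
    generate_continuous,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture
def small_continuous():
    """Small continuous dataset with mild noise plus its truth and design."""
    cfg = ContinuousSimConfig(n=300, p=4, T=4, k=2, r=2, d1=2, d2=2,
                              noise_scale=0.3, seed=7)
    data, truth = generate_continuous(cfg)
    design = build_fourier(data.y, 2, 2)
    return data, truth, design


@pytest.fixture
def noiseless_continuous():
    cfg = ContinuousSimConfig(n=200, p=4, T=4, k=2, r=2, d1=2, d2=2,
                              noise_scale=0.0, seed=3)
    data, truth = generate_continuous(cfg)
    design = build_fourier(data.y, 2, 2)
    return data, truth, design


@pytest.fixture
def binary_data():
    cfg = BinarySimConfig(n_per_group=200, seed=11)
    data, truth = generate_binary(cfg)
    return data, truth


def make_dataset(rng, n=20, p=3, T=2):
    return MatrixDataset(rng.standard_normal((n, p, T)), rng.standard_normal(n))
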