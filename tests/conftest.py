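import numpy as np
import pytest

import cestdisc as cd


@pytest.fixture(scope="session")
def creatine_noiseless():
    """Small noiseless creatine phantom dataset (fast, deterministic)."""
    spec = cd.make_creatine_phantom(grid=(48, 48), seed=11, snr=np.inf)
    epi, rare, gt = cd.simulate_dataset(spec)
    return spec, epi, rare, gt


@pytest.fixture(scope="session")
def creatine_snr40():
    spec = cd.make_creatine_phantom(grid=(48, 48), seed=11, snr=40.0)
    epi, rare, gt = cd.simulate_dataset(spec)
    return spec, epi, rare, gt


@pytest.fixture(scope="session")
def brain_tumor_noiseless():
    spec = cd.make_brain_phantom(grid=(48, 48), seed=5, snr=np.inf, with_tumor=True)
    epi, rare, gt = cd.simulate_dataset(spec)
    return spec, epi, rare, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
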