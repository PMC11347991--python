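import numpy as np
import pytest

from flimplex import DecayParams, IRFModel, TimingConfig


@pytest.fixture(scope="session")
def timing() -> TimingConfig:
    return TimingConfig()  # 12.5 ns period, 256 bins


@pytest.fixture(scope="session")
def fine_timing() -> TimingConfig:
    """Dense binning for closed-form comparisons with small discretization."""
    return TimingConfig(period_ns=12.5, n_bins=4096)


@pytest.fixture(scope="session")
def delta_irf() -> IRFModel:
    return IRFModel(kind="delta", center_t0=0.0, fwhm=0.0)


@pytest.fixture(scope="session")
def gauss_irf() -> IRFModel:
    return IRFModel()  # gaussian, fwhm 0.2 ns, t0 2.0 ns


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def biexp_params() -> DecayParams:
    return DecayParams((0.6, 0.4), (0.8, 2.4))
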