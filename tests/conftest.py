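import numpy as np
import pytest

from powerpost.dcm_fmri import add_noise_at_snr, integrate_dcm, make_fixture_models
from powerpost.model_core import generate_linreg_dataset


@pytest.fixture(scope="session")
def fixture_specs():
    """The five 3-region DCMs at full acquisition length (720 scans)."""
    return make_fixture_models()


@pytest.fixture(scope="session")
def short_specs():
    """Same five DCMs at 80 scans, for fast unit tests."""
    return make_fixture_models(n_scans=80)


@pytest.fixture(scope="session")
def m1_dataset(fixture_specs):
    """Noisy BOLD simulated from the linear model m1 at SNR = 1."""
    signal = integrate_dcm(fixture_specs[0])
    return add_noise_at_snr(signal, snr=1.0, seed=424242)


@pytest.fixture()
def linreg_small():
    """A p=4, M=100 conjugate regression dataset with the benchmark precisions."""
    return generate_linreg_dataset(4, 100, prior_var=16.0, noise_var=10.0, seed=12345)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
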