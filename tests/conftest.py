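import numpy as np
import pytest

from perfaid.phantom import PhantomConfig, make_phantom
from perfaid.preprocess import preprocess


@pytest.fixture(scope="session")
def noiseless_case():
    return make_phantom(PhantomConfig(noise_sd_frac=0.0), seed=11)


@pytest.fixture(scope="session")
def noisy_case():
    return make_phantom(PhantomConfig(noise_sd_frac=0.1), seed=11)


@pytest.fixture(scope="session")
def noiseless_conc(noiseless_case):
    return preprocess(noiseless_case.series, sigma_mm=0.0)


@pytest.fixture(scope="session")
def small_series():
    """Tiny deterministic 4D series for I/O and layout tests."""
    from perfaid.datamodel import PerfusionSeries

    rng = np.random.default_rng(0)
    sig = rng.random((8, 8, 3, 5)).astype(np.float32)
    return PerfusionSeries(
        signal=sig, tr_s=1.5, te_s=0.0026, voxel_mm=np.array([0.43, 0.43, 5.0])
    )
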