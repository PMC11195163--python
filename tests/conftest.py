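import numpy as np
import pytest

from idpbind.datasets import SERF_YEAST, TAR_HIV1
from idpbind.geometry import NullChainModel
from idpbind.synthetic import sample_frc_ensemble


@pytest.fixture(scope="session")
def serf():
    return SERF_YEAST


@pytest.fixture(scope="session")
def tar():
    return TAR_HIV1


@pytest.fixture(scope="session")
def frc_chain():
    return NullChainModel()


@pytest.fixture(scope="session")
def frc_ensemble_small():
    """2,000-frame freely-rotating-chain ensemble of a 68-mer."""
    return sample_frc_ensemble(68, n_frames=2000, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
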