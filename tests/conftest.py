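import numpy as np
import pytest

from pvcircuit.ensemble import StimulusEnsemble, default_ensemble
from pvcircuit.synthgen import gen_dataset, ConnectivityParams


@pytest.fixture(scope="session")
def ensemble():
    return default_ensemble()


@pytest.fixture(scope="session")
def small_ensemble():
    """Reduced grid for fast fitting tests."""
    return StimulusEnsemble(
        directions=np.arange(4) * 90.0,
        spatial_freqs=0.01 * 2.0 ** np.arange(3),
        temporal_freqs=0.5 * 2.0 ** np.arange(3),
        n_stationary_frames=2,
        n_moving_frames=4,
    )


@pytest.fixture(scope="session")
def paired_dataset():
    """Moderate synthetic dataset shared across statistics tests."""
    return gen_dataset(n_pv=8, n_pyr=40, n_rep=6, seed=11,
                       connectivity=ConnectivityParams(pyr_per_pv=5))
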