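import numpy as np
import pytest
from hypothesis import settings

from subfbm import FbmParams, WaitingTimeModel, simulate_ensemble

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_ctrw_ensemble():
    """Modest CTRW ensemble (alpha=0.7, Brownian steps) shared by tests that
    only need qualitative heavy-tail behaviour."""
    return simulate_ensemble(WaitingTimeModel(0.7), FbmParams(0.5),
                             t_m=2**10, dt=1.0, n_real=400, seed=99)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
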