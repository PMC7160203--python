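import numpy as np
import pytest

from boldvar.core import BoldRun
from boldvar.synthdata import PhantomConfig, make_masks


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale phantom grid used across tests."""
    return PhantomConfig(grid_shape=(16, 16, 12), groups={"HC": 4, "aMCI": 4, "AD": 4})


@pytest.fixture(scope="session")
def small_masks(small_config):
    return make_masks(small_config)


@pytest.fixture(scope="session")
def default_masks():
    return make_masks(PhantomConfig())


def make_run(data, tr_s=2.3, mask=None):
    """BoldRun around a (x, y, z, t) array with a full (or given) mask."""
    data = np.asarray(data, dtype=float)
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    return BoldRun(data=data, tr_s=tr_s, brain_mask=mask)


@pytest.fixture
def noise_run():
    """Small white-noise run, full mask."""
    rng = np.random.default_rng(42)
    return make_run(rng.normal(0, 1, size=(4, 4, 3, 125)))
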