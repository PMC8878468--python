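import numpy as np
import pytest

from cytogate.synth import RenderParams


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_params():
    """Fast small-field render parameters used across the suite."""
    return RenderParams(shape=(256, 256), n_z=3, z_focus=1)


@pytest.fixture
def medium_params():
    return RenderParams(shape=(400, 400), n_z=3, z_focus=1)
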