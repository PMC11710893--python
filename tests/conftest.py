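import numpy as np
import pytest

from eegworkload.layout import make_layout
from eegworkload.synth import make_canonical_templates


@pytest.fixture(scope="session")
def layout():
    return make_layout()


@pytest.fixture(scope="session")
def canon(layout):
    return make_canonical_templates(layout)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_zero_mean_maps(rng, n_maps, n_channels):
    """Random average-referenced topographies (rows)."""
    maps = rng.standard_normal((n_maps, n_channels))
    return maps - maps.mean(axis=1, keepdims=True)
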