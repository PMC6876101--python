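import logging

import numpy as np
import pytest

from oncowalk import DiseaseSimilarity, WalkParams
from oncowalk.simulate import FixtureConfig, generate

logging.getLogger("oncowalk").setLevel(logging.ERROR)
logging.getLogger("oncowalk.assembly").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config():
    """Planted fixture small enough for per-test LOOCV runs."""
    return FixtureConfig(
        n_genes=60,
        n_mirnas=12,
        n_lncrnas=12,
        n_cancers=4,
        n_modules=4,
        module_size=5,
        signal=0.9,
        enrichment=6.0,
        n_complexes=10,
        knn_mirna=5,
        knn_lncrna=5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate(small_config)


@pytest.fixture(scope="session")
def small_net(small_bundle):
    net, complexes = small_bundle.to_network()
    return net, complexes


@pytest.fixture(scope="session")
def default_params():
    return WalkParams()


@pytest.fixture
def dsim4():
    """Hand-built 4-disease similarity matrix used by the formula examples."""
    values = np.array(
        [
            [1.0, 0.3, 0.7, 0.5],
            [0.3, 1.0, 0.4, 0.2],
            [0.7, 0.4, 1.0, 0.6],
            [0.5, 0.2, 0.6, 1.0],
        ]
    )
    return DiseaseSimilarity(("x", "y", "z", "w"), values)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
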