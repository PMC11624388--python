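import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cownet.covariates import build_dyad_covariates
from cownet.geometry import BarnGeometry, default_barn
from cownet.synthetic import generate_herd
from shapely.geometry import Polygon


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def barn():
    return default_barn()


@pytest.fixture(scope="session")
def small_barn():
    """Compact two-area barn for fast trajectory tests."""
    return BarnGeometry(
        width=40.0,
        height=20.0,
        resting=(Polygon([(0, 7), (36, 7), (36, 13), (0, 13)]),),
        feeding=(
            Polygon([(0, 0), (36, 0), (36, 6), (0, 6)]),
            Polygon([(0, 14), (36, 14), (36, 20), (0, 20)]),
        ),
        excluded=(Polygon([(36, 0), (40, 0), (40, 20), (36, 20)]),),
    )


@pytest.fixture(scope="session")
def herd75():
    return generate_herd(75, 10, seed=1)


@pytest.fixture(scope="session")
def cov75(herd75):
    herd, ped = herd75
    return build_dyad_covariates(ped, herd, herd["cow_id"])


@pytest.fixture(scope="session")
def herd20():
    return generate_herd(20, 4, seed=7)


@pytest.fixture(scope="session")
def cov20(herd20):
    herd, ped = herd20
    return build_dyad_covariates(ped, herd, herd["cow_id"])
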