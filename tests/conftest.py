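import numpy as np
import pytest

from spac.experiments import ExperimentConfig, run_e1, run_e2
from spac.forcing import ForcingRecord, vpd_from_rh
from spac.gasx import GasExchangeParams
from spac.hydro import PlantTraits


@pytest.fixture
def gp():
    return GasExchangeParams()


@pytest.fixture
def traits():
    return PlantTraits()


def make_record(ta=30.0, rh=0.25, sw=850.0, patm=101325.0, ca=400.0):
    return ForcingRecord(
        Ta=ta, RH=rh, SWdown=sw, Patm=patm, wind=2.0, precip=0.0,
        ca=ca, D=vpd_from_rh(ta, rh),
    )


@pytest.fixture
def day_record():
    return make_record()


@pytest.fixture
def night_record():
    return make_record(ta=18.0, rh=0.6, sw=0.0)


@pytest.fixture(scope="session")
def e1_results():
    """Full 250-day dry-down (E1a) for baseline, H and HC on the default traits."""
    return run_e1(ExperimentConfig(scenario="e1a", n_days=250))


@pytest.fixture(scope="session")
def e2_results():
    """Dry-down to fs=0.2 plus saturating relief (E2a) for HC and HC-d."""
    return run_e2(ExperimentConfig(scenario="e2a"))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
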