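import numpy as np
import pytest

import pvsignal as pv

TARGET = "CYCLOBENZAPRINE"


@pytest.fixture(scope="session")
def small_config():
    """A small planted-signal database: 5,000 cases, one strong signal."""
    return pv.SyntheticConfig(
        n_cases=5_000,
        seed=7,
        planted_signals=(pv.PlantedSignal("PT_0050", 10.0),),
    )


@pytest.fixture(scope="session")
def small_tables(small_config):
    return pv.generate(small_config)


@pytest.fixture(scope="session")
def small_cases(small_tables):
    return pv.assemble_cases(small_tables)


@pytest.fixture(scope="session")
def small_split(small_cases):
    return pv.filter_primary_suspect(small_cases, TARGET)


@pytest.fixture(scope="session")
def example_table():
    """The hand-computable 2x2 table: a=20, b=80, c=100, d=9800."""
    return pv.ContingencyTable(term="X", level="PT", a=20, b=80, c=100, d=9800)


@pytest.fixture(scope="session")
def canonical_prior():
    return pv.MgpsPrior(0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
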