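import numpy as np
import pytest

import protonshift as ps
from protonshift.gnn import GraphConfig


@pytest.fixture(scope="session")
def ethyl_acetate():
    return ps.parse_structure("CCOC(C)=O", "ethyl-acetate")


@pytest.fixture(scope="session")
def methanol():
    return ps.parse_structure("CO", "methanol")


@pytest.fixture(scope="session")
def benzene():
    return ps.parse_structure("c1ccccc1", "benzene")


@pytest.fixture(scope="session")
def reduced_config():
    return GraphConfig.reduced()


@pytest.fixture(scope="session")
def tiny_config():
    # very small model for fast structural tests
    return GraphConfig(n_rbf=8, dim=16, readout_widths=(16, 12, 8))


@pytest.fixture(scope="session")
def synthetic_pool():
    """Twenty small synthetic molecules with noiseless oracle labels."""
    molecules, records = ps.make_dataset(20, ps.OracleParams(), 0.0, seed=11)
    return molecules, records
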