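import numpy as np
import pytest

from ppmatch import run_exp1, trials_to_dataframe
from ppmatch.synthetic_experiment import ProtocolConfig


@pytest.fixture(scope="session")
def exp1_map_run():
    """One full long-design session from a MAP observer with rho = 1."""
    cfg = ProtocolConfig.exp1(rule="map", rho=1.0)
    records = run_exp1(cfg, np.random.default_rng(20260401))
    return cfg, records


@pytest.fixture(scope="session")
def exp1_map_df(exp1_map_run):
    _, records = exp1_map_run
    return trials_to_dataframe(records, debug=True)
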