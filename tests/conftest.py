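import numpy as np
import pytest

from hoxsurvey.assign import AssignConfig, Assigner
from hoxsurvey.primers import load_primer_table
from hoxsurvey.simulate import evolve_panel


@pytest.fixture(scope="session")
def primers():
    return load_primer_table()


@pytest.fixture(scope="session")
def primer_map(primers):
    return {p.name: p for p in primers}


@pytest.fixture(scope="session")
def panel():
    """Synthetic 3-species reference panel evolved from the packaged roots."""
    return evolve_panel(seed=1)


@pytest.fixture(scope="session")
def assigner(panel):
    return Assigner(panel, AssignConfig(n_bootstrap=100), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240001)
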