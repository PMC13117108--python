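import numpy as np
import pytest

from parbid.insilico_pcr import default_panel
from parbid.synth import PanelSimSpec, simulate_species_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def sim_panel():
    """Default 7-species PARB-like panel with queries and truth table."""
    spec = PanelSimSpec(seed=1)
    refs, queries, truth = simulate_species_panel(spec)
    return refs, queries, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
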