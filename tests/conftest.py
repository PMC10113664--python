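import numpy as np
import pytest

from phytoscreen.synthdata import SynthConfig


@pytest.fixture
def small_config():
    """A scaled-down generator configuration for fast unit tests."""
    return SynthConfig(
        n_drugs=6,
        n_effective_drugs=3,
        compounds_per_drug=(10, 20),
        n_genes=120,
        n_communities=3,
        disease_module_size=20,
        community_set_size=15,
        n_patients=200,
        n_control_patients=200,
        n_background_drugs=10,
        n_eligible_treated=120,
        n_eligible_control=120,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
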