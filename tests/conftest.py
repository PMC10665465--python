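import numpy as np
import pytest

from angiodiv import SimulationConfig, parse_newick, simulate_dataset


@pytest.fixture
def three_tip_tree():
    return parse_newick("((A:1,B:1):2,C:3);")


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic study shared by read-only tests."""
    return simulate_dataset(SimulationConfig(seed=42, n_tips=80, n_units=40))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
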