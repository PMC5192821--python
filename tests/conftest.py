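import numpy as np
import pytest

from phet.simulate import SimulationConfig, simulate_tree
from phet.tree import parse_newick

#: three tips, unit-height cherry (A,B) plus outgroup C at depth 2
EXAMPLE_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def example_tree():
    return parse_newick(EXAMPLE_NEWICK)


@pytest.fixture
def example_dist(example_tree):
    return example_tree.pairwise_distances()


@pytest.fixture(params=[11, 23, 47])
def random_tree(request):
    """Yule trees of assorted sizes for property checks."""
    return simulate_tree(20, np.random.default_rng(request.param))


@pytest.fixture
def small_sim_config():
    """Desk-scale generator settings for fast end-to-end tests."""
    return SimulationConfig(n_plots=8, pool_size=24, stems_range=(30, 60), seed=7)
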