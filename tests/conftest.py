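import numpy as np
import pytest

from viperpcm.synth import simulate_yule_tree
from viperpcm.treeops import Chronogram, phylo_covariance


@pytest.fixture
def three_tip():
    """((A:1,B:1):3,C:4): the standard small worked example."""
    return Chronogram.from_newick("((A:1,B:1):3,C:4);")


@pytest.fixture(scope="session")
def yule39():
    """One fixed 39-tip Yule chronogram at 26 My crown age."""
    return simulate_yule_tree(39, seed=11, depth=26.0)


@pytest.fixture(scope="session")
def yule39_cov(yule39):
    return phylo_covariance(yule39)


@pytest.fixture
def star_cov():
    """Equal-depth star phylogeny covariance (t * I) for 10 tips."""
    return 5.0 * np.eye(10)
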