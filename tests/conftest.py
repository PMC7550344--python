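import numpy as np
import pytest

from paleophys.phylo import parse_newick
from paleophys.simulate import SimConfig


@pytest.fixture
def balanced_tree():
    """Four-tip ultrametric tree of height 2."""
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def cherry_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def base_config():
    return SimConfig(n_tips=20, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
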