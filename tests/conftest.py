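import numpy as np
import pytest

from hostphylo.trees import parse_newick


@pytest.fixture
def three_tip_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
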