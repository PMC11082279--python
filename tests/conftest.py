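import numpy as np
import pytest

from ldagnn.io import AssociationMatrix
from ldagnn.subgraph import build_bipartite_graph


@pytest.fixture
def toy_assoc():
    """The 3-edge toy: L1-{D1,D2}, L2-D2."""
    return AssociationMatrix.from_pairs([("L1", "D1"), ("L1", "D2"),
                                         ("L2", "D2")])


@pytest.fixture
def toy_graph(toy_assoc):
    return build_bipartite_graph(toy_assoc)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
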