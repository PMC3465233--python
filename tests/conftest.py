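import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper module

from tfko import EdgeRecord, SupportMode, build_network
from tfko.examples import example_network, example_targets


@pytest.fixture(scope="session")
def fig_network():
    """The worked-example network: Hsf1/Rpn4 chain plus Stp2/Adr1 chain."""
    return example_network()


@pytest.fixture(scope="session")
def fig_targets():
    return example_targets()


def network_from_adjacency(matrix: np.ndarray, regulation_prob: float = 0.0,
                           rng: np.random.Generator | None = None):
    """Build a RegulatoryNetwork from a boolean adjacency matrix with node
    names N00, N01, ..."""
    n = matrix.shape[0]
    names = [f"N{i:02d}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(n):
            if matrix[i, j]:
                regulation = bool(rng.random() < regulation_prob) if rng else False
                edges.append(EdgeRecord(names[i], names[j], True, regulation))
    return build_network(edges, SupportMode.BINDING), names
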