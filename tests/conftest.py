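import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from trigat import KnowledgeGraph

# property tests must be reproducible run to run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_graph(n_nodes=8, edges=((0, 1), (1, 2), (2, 3), (3, 0), (4, 5)),
               edge_dim=3, feat_dim=4, positives=(0, 5), seed=0) -> KnowledgeGraph:
    """A small deterministic KnowledgeGraph for unit tests."""
    rng = np.random.default_rng(seed)
    src = np.array([e[0] for e in edges], dtype=np.int64)
    dst = np.array([e[1] for e in edges], dtype=np.int64)
    E = (rng.random((len(edges), edge_dim)) < 0.6).astype(float)
    E[E.sum(axis=1) == 0, 0] = 1.0
    X = rng.standard_normal((n_nodes, feat_dim))
    y = np.full(n_nodes, -1, dtype=np.int64)
    y[list(positives)] = 1
    ids = [f"G{i:03d}" for i in range(n_nodes)]
    return KnowledgeGraph(ids, src, dst, E, X, y,
                          provenance={"positive": {ids[i] for i in positives},
                                      "sampled_negative": set()})


@pytest.fixture
def tiny_graph():
    return make_graph()
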