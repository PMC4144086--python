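import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from nimclass.dataio import ExpressionDataset
from nimclass.synth import example_graph


@pytest.fixture
def six_node_graph():
    """The printed six-node 0/1 worked-example network."""
    return example_graph()


@pytest.fixture
def rng():
    return np.random.default_rng(20140811)


@pytest.fixture
def tiny_dataset():
    """3 samples x 4 features, labeled."""
    return ExpressionDataset(
        sample_ids=["s1", "s2", "s3"],
        feature_ids=["g1", "g2", "g3", "g4"],
        values=[[0.0, 5.0, 1.0, 7.0], [5.0, 0.0, 2.0, 7.0], [10.0, 2.5, 3.0, 7.0]],
        labels=["A", "B", "A"],
    )


# 6 training + 2 test samples in 2-D with printed coordinates; two
# well-separated classes, used for the end-to-end pipeline oracle checks.
TRAIN_XY = [
    [0.10, 0.20],
    [0.20, 0.10],
    [0.15, 0.30],
    [0.80, 0.90],
    [0.90, 0.80],
    [0.85, 0.70],
]
TRAIN_LABELS = ["A", "A", "A", "B", "B", "B"]
TEST_XY = [[0.20, 0.20], [0.80, 0.80]]


@pytest.fixture
def planar_split():
    train = ExpressionDataset(
        sample_ids=[f"tr{i}" for i in range(6)],
        feature_ids=["x", "y"],
        values=TRAIN_XY,
        labels=TRAIN_LABELS,
    )
    test = ExpressionDataset(
        sample_ids=["te0", "te1"],
        feature_ids=["x", "y"],
        values=TEST_XY,
    )
    return train, test


def random_connected_nonbipartite(rng, n_max=8, weighted=False, k_check=200, tol=1e-8):
    """Rejection-sample a connected non-bipartite undirected graph.

    Graphs whose relative spectral gap is so small that ``k_check``
    walk steps cannot contract below ``tol`` are also rejected: the
    walk ratio converges at rate (|lambda_2|/|lambda_1|)^k, so the
    finite-k comparison is only meaningful above that rate.
    """
    from nimclass.graph import WeightedGraph
    from nimclass.influence import check_convergence

    while True:
        n = int(rng.integers(3, n_max + 1))
        a = (rng.random((n, n)) < 0.5).astype(float)
        a = np.triu(a, 1)
        a = a + a.T
        if weighted:
            w = rng.uniform(0.1, 1.0, size=(n, n))
            w = np.triu(w, 1)
            a = a * (w + w.T)
        g = WeightedGraph([str(i) for i in range(n)], a)
        diag = check_convergence(g)
        if not (diag.connected and not diag.bipartite):
            continue
        lam1 = np.max(np.abs(np.linalg.eigvalsh(a)))
        ratio = (lam1 - diag.gap) / lam1
        if ratio**k_check < tol / 10:
            return g
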