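"""Distance matrices and dense Gaussian similarity graphs over samples.

Every pair of samples is connected by an edge whose weight is the
Gaussian (RBF) kernel of their distance, ``exp(-d^2 / (2 delta^2))``,
with bandwidth ``delta``. Over distinct samples the resulting graph is
complete with strictly positive weights, hence connected and (for three
or more nodes) non-bipartite — exactly the regime in which the
walk-ratio centrality converges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from nimclass.dataio import ExpressionDataset

#: metric names accepted by distance_matrix (scipy pdist spellings)
METRICS = ("euclidean", "cityblock", "chebyshev", "cosine")

DIAGONAL_POLICIES = ("zero", "one")
EXPONENT_CONVENTIONS = ("squared", "raw")


@dataclass
class WeightedGraph:
    """Symmetric nonnegative edge-weight matrix over named nodes."""

    node_ids: list
    weights: np.ndarray
    delta: Optional[float] = None

    def __post_init__(self):
        self.node_ids = [str(n) for n in self.node_ids]
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.node_ids)
        if self.weights.shape != (n, n):
            raise ValueError(
                f"weight matrix shape {self.weights.shape} does not match "
                f"{n} node ids"
            )
        if len(set(self.node_ids)) != n:
            raise ValueError("duplicate node ids")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite edge weight")
        if np.any(self.weights < 0):
            raise ValueError("negative edge weight")
        if not np.allclose(self.weights, self.weights.T, rtol=0, atol=1e-12):
            raise ValueError("weight matrix is not symmetric")
        # exact symmetry simplifies spectral code downstream
        self.weights = (self.weights + self.weights.T) / 2.0

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def index_of(self, node) -> int:
        """Resolve a node reference (id string or integer index)."""
        if isinstance(node, (int, np.integer)):
            n = self.n_nodes
            if not 0 <= node < n:
                raise IndexError(f"node index {node} out of range [0, {n})")
            return int(node)
        node = str(node)
        try:
            return self.node_ids.index(node)
        except ValueError:
            raise KeyError(f"unknown node id {node!r}") from None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.weights, index=self.node_ids, columns=self.node_ids)
        df.index.name = "node_id"
        return df

    def write(self, path, delimiter: str = "\t") -> None:
        """Dump the weight matrix as delimited text for inspection."""
        self.to_frame().to_csv(path, sep=delimiter)


def euclidean_distance(x, y) -> float:
    """Root-sum-of-squares distance between two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(np.sqrt(np.sum((x - y) ** 2)))


def distance_matrix(dataset: ExpressionDataset, metric: str = "euclidean") -> np.ndarray:
    """Pairwise sample distance matrix (zero diagonal, symmetric)."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if dataset.n_samples == 1:
        return np.zeros((1, 1))
    return squareform(pdist(dataset.values, metric=metric))


def similarity(d, delta: float, exponent: str = "squared"):
    """Gaussian edge weight for a distance.

    With the default ``exponent="squared"`` this is the standard RBF
    kernel ``exp(-d^2 / (2 delta^2))``; ``exponent="raw"`` applies the
    kernel to the unsquared distance, ``exp(-d / (2 delta^2))``, for
    reproduction studies using that convention.
    """
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    if exponent not in EXPONENT_CONVENTIONS:
        raise ValueError(
            f"unknown exponent convention {exponent!r}; "
            f"choose from {EXPONENT_CONVENTIONS}"
        )
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    num = d**2 if exponent == "squared" else d
    out = np.exp(-num / (2.0 * delta**2))
    return float(out) if out.ndim == 0 else out


def build_graph(
    dataset: ExpressionDataset,
    delta: float,
    diagonal_policy: str = "zero",
    metric: str = "euclidean",
    exponent: str = "squared",
) -> WeightedGraph:
    """Build the dense similarity graph over all samples of a dataset.

    ``W(i, j) = similarity(D(i, j), delta)`` off the diagonal; the
    diagonal is forced to 0 (default, no self-loops) or 1. A uniform
    diagonal shift does not change eigenvectors, so the choice does not
    affect the node-influence centrality.
    """
    if diagonal_policy not in DIAGONAL_POLICIES:
        raise ValueError(
            f"unknown diagonal policy {diagonal_policy!r}; "
            f"choose from {DIAGONAL_POLICIES}"
        )
    d = distance_matrix(dataset, metric=metric)
    w = similarity(d, delta, exponent=exponent)
    np.fill_diagonal(w, 0.0 if diagonal_policy == "zero" else 1.0)
    return WeightedGraph(node_ids=list(dataset.sample_ids), weights=w, delta=delta)
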