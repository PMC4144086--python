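"""Walk-counting node influence and its eigenvector limit.

The entry ``A^k(i, j)`` of the k-th power of an adjacency matrix counts
(weighted) walks of length k between nodes i and j. The k-step
influence of node i on node j is the fraction of all k-walks ending at
j that start at i,

    influence_k(i -> j) = A^k(i, j) / sum_m A^k(m, j).

For a connected, non-bipartite undirected graph this ratio converges as
k grows to a limit independent of j: the i-th component of the
entrywise-positive leading (Perron) eigenvector of A, normalized to sum
to one. That limit is the node-influence centrality. Bipartite graphs
are the excluded case: their spectrum is symmetric about zero, the two
extreme eigenvalues tie in absolute value, and the ratio oscillates
with the parity of k instead of converging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import connected_components

from nimclass.graph import WeightedGraph

__all__ = [
    "InfluenceVector",
    "ConvergenceDiagnostic",
    "BipartiteGraphError",
    "DisconnectedGraphError",
    "walk_influence",
    "walk_influence_trace",
    "node_influence",
    "check_convergence",
]

# relative tolerance for deciding the leading eigenvalue is repeated
_EIG_MULTIPLICITY_RTOL = 1e-10
# residual tolerance ||A v - lambda v||_inf for the returned eigenpair
_EIG_RESIDUAL_TOL = 1e-10
# rescale intermediate matrix powers only outside this range, so small-k
# integer-adjacency results stay exact while large k cannot under/overflow
_RESCALE_LO, _RESCALE_HI = 1e-50, 1e50


class DisconnectedGraphError(ValueError):
    """The graph is not connected; the walk-ratio limit is undefined."""


class BipartiteGraphError(ValueError):
    """The graph is bipartite; the walk ratio oscillates and has no limit."""


@dataclass
class ConvergenceDiagnostic:
    """Preconditions for convergence of the walk-ratio centrality.

    ``gap`` is |lambda_1| minus the largest remaining |lambda|; a zero
    gap (bipartite or disconnected graphs) means the finite-k ratio
    does not converge. ``leading_multiplicity`` counts eigenvalues
    numerically equal to lambda_max (always 1 for connected graphs).
    """

    connected: bool
    bipartite: bool
    gap: float
    leading_multiplicity: int = 1

    @property
    def converges(self) -> bool:
        return self.connected and not self.bipartite and self.gap > 0


@dataclass
class InfluenceVector:
    """Per-node influence weights summing to one."""

    node_ids: list
    values: np.ndarray
    method: str = "eigen"
    k_used: Union[int, str] = "limit"
    gap: Optional[float] = None

    def __post_init__(self):
        self.node_ids = [str(n) for n in self.node_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.node_ids),):
            raise ValueError("values length does not match node ids")

    def __getitem__(self, node) -> float:
        if isinstance(node, (int, np.integer)):
            return float(self.values[int(node)])
        return float(self.values[self.node_ids.index(str(node))])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"node_id": self.node_ids, "influence": self.values}
        ).set_index("node_id")

    def write(self, path, delimiter: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=delimiter)


def _matrix_powers(a: np.ndarray, k: int):
    """Yield (A^1, ..., A^k) up to a positive per-matrix scale factor.

    Each power is rescaled by its max entry only when entries leave a
    wide safe range; the walk ratio is invariant to any positive scale.
    """
    p = a.copy()
    for _ in range(k):
        yield p
        m = p.max()
        if m > 0 and not (_RESCALE_LO < m < _RESCALE_HI):
            p = p / m
        p = p @ a


def walk_influence(graph: WeightedGraph, i, j, k: int) -> float:
    """Fraction of k-length walks ending at j that start at i.

    Computed by iterated matrix multiplication (k - 1 multiplies), so
    the result is exact for 0/1 adjacencies at small k.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    ii = graph.index_of(i)
    jj = graph.index_of(j)
    a = graph.weights
    for p in _matrix_powers(a, k):
        pass
    col = p[:, jj]
    denom = col.sum()
    if denom == 0:
        raise ZeroDivisionError(
            f"no walks of length {k} end at node {graph.node_ids[jj]!r}"
        )
    return float(col[ii] / denom)


def walk_influence_trace(graph: WeightedGraph, i, j, k_max: int) -> np.ndarray:
    """Influence of i on j for every k = 1..k_max (a convergence trace)."""
    if k_max < 1:
        raise ValueError(f"k_max must be >= 1, got {k_max}")
    ii = graph.index_of(i)
    jj = graph.index_of(j)
    out = np.empty(k_max)
    for idx, p in enumerate(_matrix_powers(graph.weights, k_max)):
        denom = p[:, jj].sum()
        out[idx] = p[ii, jj] / denom if denom > 0 else np.nan
    return out


def check_convergence(graph: WeightedGraph) -> ConvergenceDiagnostic:
    """Diagnose whether the walk-ratio centrality converges on a graph.

    Connectivity and 2-colorability are checked on the unweighted
    support of the weight matrix; the spectral gap on the weights.
    Never raises.
    """
    a = graph.weights
    n = graph.n_nodes
    support = (a > 0).astype(int)
    n_comp, _ = connected_components(support, directed=False)
    connected = bool(n_comp == 1)
    g = nx.from_numpy_array(support)
    bipartite = bool(nx.is_bipartite(g))
    if np.any(np.diag(a) > 0):
        bipartite = False  # self-loops are odd closed walks
    evals = np.linalg.eigvalsh(a)  # ascending
    abs_desc = np.sort(np.abs(evals))[::-1]
    gap = float(abs_desc[0] - abs_desc[1]) if n > 1 else float(abs_desc[0])
    lead = evals[-1]
    mult = int(
        np.sum(np.abs(evals - lead) <= _EIG_MULTIPLICITY_RTOL * max(1.0, abs(lead)))
    )
    return ConvergenceDiagnostic(
        connected=connected, bipartite=bipartite, gap=gap, leading_multiplicity=mult
    )


def _perron_power(a: np.ndarray, tol: float, maxiter: int = 200_000) -> np.ndarray:
    """Leading eigenvector of a nonnegative symmetric matrix by power
    iteration from a uniform positive start (iterates stay nonnegative)."""
    n = a.shape[0]
    v = np.full(n, 1.0 / np.sqrt(n))
    lam = 0.0
    for _ in range(maxiter):
        av = a @ v
        lam = np.linalg.norm(av)
        if lam == 0:
            raise ArithmeticError("power iteration hit the zero vector")
        v_new = av / lam
        if np.max(np.abs(a @ v_new - lam * v_new)) <= tol:
            return v_new
        v = v_new
    raise ArithmeticError(
        f"power iteration did not reach residual {tol:.3e} in {maxiter} steps"
    )


def node_influence(
    graph: WeightedGraph, method: str = "eigen", k: int = 200
) -> InfluenceVector:
    """The limiting node-influence centrality of every node.

    With ``method="eigen"`` (the definition) the vector is the
    entrywise-positive leading eigenvector of the weight matrix,
    normalized to sum to one. ``method="power_k"`` instead returns the
    finite-k walk ratio ``A^k(:, j) / sum A^k(:, j)`` (any column j;
    they agree in the limit), for validation and convergence studies.

    Raises :class:`DisconnectedGraphError` or
    :class:`BipartiteGraphError` when the limit does not exist.
    """
    diag = check_convergence(graph)
    if not diag.connected:
        raise DisconnectedGraphError(
            "graph is disconnected: the walk-ratio limit is undefined"
        )
    if diag.bipartite:
        raise BipartiteGraphError(
            "graph is bipartite: the extreme eigenvalues tie in absolute "
            "value and the walk ratio oscillates instead of converging"
        )

    if method == "power_k":
        a = graph.weights
        for p in _matrix_powers(a, k):
            pass
        # column whose sum is largest, for numerical headroom
        jj = int(np.argmax(p.sum(axis=0)))
        v = p[:, jj] / p[:, jj].sum()
        return InfluenceVector(
            node_ids=list(graph.node_ids),
            values=v,
            method="power_k",
            k_used=k,
            gap=diag.gap,
        )
    if method != "eigen":
        raise ValueError(f"unknown method {method!r}; choose 'eigen' or 'power_k'")

    a = graph.weights
    eigval, eigvec = np.linalg.eigh(a)
    lead = eigval[-1]
    if diag.leading_multiplicity > 1:
        # repeated leading root: sum the eigenspace basis columns
        sel = np.abs(eigval - lead) <= _EIG_MULTIPLICITY_RTOL * max(1.0, abs(lead))
        v = eigvec[:, sel].sum(axis=1)
    else:
        v = eigvec[:, -1]
        resid = np.max(np.abs(a @ v - lead * v))
        if resid > _EIG_RESIDUAL_TOL * max(1.0, abs(lead)):
            raise ArithmeticError(
                f"eigen-solver residual {resid:.3e} exceeds tolerance"
            )
    # Perron vector: fix the sign so all entries are positive
    if v.sum() < 0:
        v = -v
    if np.any(v <= 0):
        if np.min(v) < -1e-12 * np.max(np.abs(v)):
            # near-disconnected graphs: eigh loses the sign of entries many
            # orders of magnitude below the dominant block; refine with a
            # power iteration, which preserves nonnegativity exactly
            v = _perron_power(a, tol=_EIG_RESIDUAL_TOL * max(1.0, abs(lead)))
        v = np.clip(v, 0.0, None)
    v = v / v.sum()
    return InfluenceVector(
        node_ids=list(graph.node_ids),
        values=v,
        method="eigen",
        k_used="limit",
        gap=diag.gap,
    )
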