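"""Weighted network statistics: clustering coefficient and path length.

The average weighted clustering coefficient follows Fagiolo's form: each
node i scores C_i = sum_{j,k} (w_ij w_ik w_jk)^{1/3} / (k_i (k_i - 1))
where k_i counts neighbours with weight above the edge threshold tau;
CC is the mean over nodes.  With 0/1 weights this reduces exactly to the
unweighted triangle-density coefficient.

The characteristic path length CP is the mean of all-pairs shortest
weighted path lengths (Dijkstra) over ordered node pairs, after mapping
similarity weights w in (0, 1] to positive edge lengths.  Weights are
similarities, so the default transform is length = 1/w (strong
similarity = short hop); length = 1 - w is available as an alternative,
and the transform used is stamped into the result so metrics computed
under different conventions are never mixed silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .errors import (
    DisconnectedNetworkError,
    InvalidAdjacencyError,
    InvalidTransformError,
    InvalidWeightError,
)
from .network import WeightedNetwork

__all__ = [
    "NetworkMetrics",
    "unweighted_clustering_coefficient",
    "weighted_clustering_coefficient",
    "shortest_path_lengths",
    "characteristic_path_length",
    "compute_metrics",
]

TRANSFORMS = ("reciprocal", "one_minus")


@dataclass
class NetworkMetrics:
    """Summary statistics of one network.

    ``edge_definition`` is the weight threshold tau above which a pair
    counts as connected; ``length_transform`` names the weight-to-length
    map used for shortest paths.
    """

    CC: float
    CP: float
    n_nodes: int
    edge_definition: float = 0.0
    length_transform: str = "reciprocal"


def _as_weight_matrix(net: WeightedNetwork | np.ndarray) -> np.ndarray:
    if isinstance(net, WeightedNetwork):
        return net.W
    return np.asarray(net, dtype=float)


def unweighted_clustering_coefficient(A: np.ndarray) -> float:
    """Mean triangle-density clustering coefficient of a binary graph.

    Nodes of degree 0 or 1 have no neighbour pairs; they contribute a
    coefficient of 0 and are included in the average.

    Raises
    ------
    InvalidAdjacencyError
        If A is not a symmetric 0/1 matrix with zero diagonal.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise InvalidAdjacencyError(f"adjacency must be square, got {A.shape}")
    if not np.array_equal(A, A.T):
        raise InvalidAdjacencyError("adjacency must be symmetric")
    if not np.all(np.isin(A, (0.0, 1.0))):
        raise InvalidAdjacencyError("adjacency must be binary")
    if np.any(np.diag(A) != 0):
        raise InvalidAdjacencyError("adjacency diagonal must be zero")
    k = A.sum(axis=1)
    triangles = np.diag(A @ A @ A)  # 2 x number of triangles through i
    denom = k * (k - 1)
    C = np.where(denom > 0, np.divide(triangles, np.where(denom > 0, denom, 1.0)), 0.0)
    return float(C.mean())


def weighted_clustering_coefficient(
    net: WeightedNetwork | np.ndarray,
    tau: float = 0.0,
    normalize_by_max: bool = False,
    exclude_low_degree: bool = False,
) -> float:
    """Fagiolo-style mean weighted clustering coefficient.

    Parameters
    ----------
    net
        WeightedNetwork or raw symmetric weight matrix with zero
        diagonal and non-negative entries.
    tau
        Edge threshold: a pair is a neighbour pair when w > tau, and
        weights at or below tau are treated as absent.
    normalize_by_max
        Divide weights by max(w) first (Fagiolo's original scaling;
        off by default since recurrence weights already live in [0, 1]).
    exclude_low_degree
        Average C_i over nodes with degree >= 2 only, instead of
        counting degree-0/1 nodes as 0.
    """
    W = _as_weight_matrix(net)
    if np.any(W < 0):
        raise InvalidWeightError("edge weights must be non-negative")
    W = np.where(W > tau, W, 0.0)
    np.fill_diagonal(W, 0.0)
    if normalize_by_max and W.max() > 0:
        W = W / W.max()
    k = (W > 0).sum(axis=1).astype(float)
    Wc = np.cbrt(W)
    num = np.diag(Wc @ Wc @ Wc)
    denom = k * (k - 1)
    valid = denom > 0
    C = np.where(valid, np.divide(num, np.where(valid, denom, 1.0)), 0.0)
    if exclude_low_degree:
        if not np.any(valid):
            return 0.0
        return float(C[valid].mean())
    return float(C.mean())


def _length_matrix(W: np.ndarray, transform: str, tau: float) -> np.ndarray:
    """Map similarity weights to edge lengths; absent edges become 0."""
    if transform not in TRANSFORMS:
        raise InvalidTransformError(
            f"unknown transform {transform!r}; choose from {TRANSFORMS}"
        )
    mask = W > tau
    if transform == "reciprocal":
        with np.errstate(divide="ignore"):
            lengths = np.where(mask, 1.0 / np.where(mask, W, 1.0), 0.0)
    else:
        lengths = np.where(mask, 1.0 - W, 0.0)
        if np.any(mask & (lengths <= 0)):
            raise InvalidTransformError(
                "transform 'one_minus' gives non-positive length for "
                "weights >= 1; use 'reciprocal' or threshold such edges"
            )
    return lengths


def shortest_path_lengths(
    net: WeightedNetwork | np.ndarray,
    transform: str = "reciprocal",
    tau: float = 0.0,
) -> np.ndarray:
    """All-pairs shortest weighted path lengths (Dijkstra).

    Edges with weight <= tau are removed; remaining weights are mapped
    to positive lengths by ``transform``.  Unreachable pairs get +inf,
    the diagonal is 0, and the output is symmetric for symmetric input.
    """
    W = _as_weight_matrix(net)
    if np.any(W < 0):
        raise InvalidWeightError("edge weights must be non-negative")
    lengths = _length_matrix(W, transform, tau)
    graph = csr_matrix(lengths)
    return dijkstra(graph, directed=False)


def characteristic_path_length(
    net: WeightedNetwork | np.ndarray,
    transform: str = "reciprocal",
    tau: float = 0.0,
) -> float:
    """Mean shortest path length over ordered node pairs.

    Raises
    ------
    DisconnectedNetworkError
        If the thresholded network is not connected (the error carries
        the component count).
    """
    W = _as_weight_matrix(net)
    n = W.shape[0]
    if n < 2:
        raise InvalidWeightError("characteristic path length needs >= 2 nodes")
    adj = csr_matrix((W > tau).astype(float))
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp > 1:
        raise DisconnectedNetworkError(n_comp)
    D = shortest_path_lengths(W, transform=transform, tau=tau)
    off = ~np.eye(n, dtype=bool)
    return float(D[off].sum() / (n * (n - 1)))


def compute_metrics(
    net: WeightedNetwork | np.ndarray,
    tau: float = 0.0,
    transform: str = "reciprocal",
    normalize_by_max: bool = False,
    exclude_low_degree: bool = False,
) -> NetworkMetrics:
    """CC and CP of one network under a single consistent edge definition."""
    W = _as_weight_matrix(net)
    return NetworkMetrics(
        CC=weighted_clustering_coefficient(
            W, tau=tau, normalize_by_max=normalize_by_max,
            exclude_low_degree=exclude_low_degree,
        ),
        CP=characteristic_path_length(W, transform=transform, tau=tau),
        n_nodes=W.shape[0],
        edge_definition=tau,
        length_transform=transform,
    )
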