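"""Fuzzy weighted recurrence network construction.

Given an FCM membership matrix U (L points x c clusters), each pair of
data points is scored by the max-min fuzzy similarity routed through the
clusters:

    R_ab = max_i min(U_ai, U_bi)

i.e. two windows are strongly related when some cluster claims both with
high membership.  Reflexivity fixes the diagonal of the relation at 1,
and the network adjacency is W = R - I: a dense symmetric matrix of edge
weights in [0, 1] with a zero diagonal, one node per feature vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, InvalidRelationError
from .fuzzy import FCMConfig, fcm_fit, _validate_row_stochastic
from .imaging import FeatureVectorSet

__all__ = [
    "WeightedNetwork",
    "fuzzy_relation",
    "adjacency_from_relation",
    "build_network",
]

_DIAG_TOL = 1e-9


@dataclass
class WeightedNetwork:
    """Symmetric weighted network over feature-vector nodes.

    ``W`` is the L x L edge-weight matrix (symmetric, zero diagonal,
    entries in [0, 1]); ``node_coords`` maps node index to the source
    pixel (row, col); ``build_params`` records provenance (m, stride,
    c, alpha, seed).
    """

    W: np.ndarray
    node_coords: np.ndarray | None = None
    build_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise InvalidInputError(f"W must be square, got shape {W.shape}")
        if not np.allclose(W, W.T, atol=1e-12):
            raise InvalidInputError("W must be symmetric")
        if np.any(np.abs(np.diag(W)) > 0):
            raise InvalidInputError("W must have a zero diagonal")
        if np.any(W < 0) or np.any(W > 1 + 1e-12):
            raise InvalidInputError("edge weights must lie in [0, 1]")
        self.W = W

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]

    # -- serialization ------------------------------------------------

    def to_dense_csv(self, path) -> None:
        np.savetxt(path, self.W, delimiter=",")

    def to_edge_list_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node_a,node_b,weight\n")
            idx = np.triu_indices(self.n_nodes, k=1)
            for a, b in zip(*idx):
                w = self.W[a, b]
                if w > 0:
                    fh.write(f"{a},{b},{w!r}\n")

    def provenance_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"n_nodes": self.n_nodes, "build_params": self.build_params},
                fh,
                indent=2,
                default=str,
            )


def fuzzy_relation(U: np.ndarray) -> np.ndarray:
    """Max-min fuzzy relation between data points through the clusters.

    R_ab = max over clusters i of min(U_ai, U_bi) for a != b, with the
    diagonal fixed at 1 by reflexivity.  Symmetric by construction.

    Raises
    ------
    InvalidPartitionError
        If U is not row-stochastic.
    """
    U = _validate_row_stochastic(U)
    L, c = U.shape
    if L < 2:
        raise InvalidInputError("need at least 2 data points for a relation")
    R = np.zeros((L, L))
    # accumulate max over clusters without materialising the c x L x L stack
    for i in range(c):
        col = U[:, i]
        np.maximum(R, np.minimum(col[:, np.newaxis], col[np.newaxis, :]), out=R)
    np.fill_diagonal(R, 1.0)
    return R


def adjacency_from_relation(R: np.ndarray) -> WeightedNetwork:
    """Network adjacency W = R - I from a reflexive fuzzy relation.

    Off-diagonal weights are kept as-is; the unit diagonal (self
    similarity) is removed so nodes carry no self-loops.

    Raises
    ------
    InvalidRelationError
        If R is asymmetric, has a non-unit diagonal, or leaves [0, 1].
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise InvalidRelationError(f"relation must be square, got {R.shape}")
    if not np.allclose(R, R.T, atol=1e-12):
        raise InvalidRelationError("relation must be symmetric")
    if np.any(np.abs(np.diag(R) - 1.0) > _DIAG_TOL):
        raise InvalidRelationError("relation diagonal must be 1 (reflexivity)")
    if np.any(R < -1e-12) or np.any(R > 1 + 1e-12):
        raise InvalidRelationError("relation entries must lie in [0, 1]")
    W = R.copy()
    np.fill_diagonal(W, 0.0)
    return WeightedNetwork(W=np.clip(W, 0.0, 1.0))


def build_network(X: FeatureVectorSet | np.ndarray, cfg: FCMConfig) -> WeightedNetwork:
    """Fuzzy weighted recurrence network of a feature-vector set.

    Composition of the FCM fit, the max-min fuzzy relation and the
    relation-to-adjacency step, with provenance recorded on the result.
    """
    part = fcm_fit(X, cfg)
    R = fuzzy_relation(part.U)
    net = adjacency_from_relation(R)
    if isinstance(X, FeatureVectorSet):
        net.node_coords = X.coords
        net.build_params.update(X.meta)
        net.build_params["source_id"] = X.source_id
    net.build_params.update(
        {
            "c": cfg.c,
            "alpha": cfg.alpha,
            "seed": cfg.seed,
            "fcm_iterations": part.n_iter,
            "fcm_converged": part.converged,
            "partition_entropy": part.H,
        }
    )
    return net
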