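"""Fuzzy c-means clustering and partition-entropy model selection.

Fuzzy c-means (FCM) assigns every feature vector x_n a graded membership
mu_nj in [0, 1] to each of c clusters with centers v_j, alternating two
closed-form updates until the membership matrix stabilises:

* centers: v_j = sum_n mu_nj^alpha x_n / sum_n mu_nj^alpha
* memberships: mu_nj = 1 / sum_i (d_nj / d_ni)^(2/(alpha-1))

with d_nj the Euclidean distance from x_n to v_j and alpha > 1 the
fuzziness exponent.  Iteration stops when the Frobenius norm of the
membership change drops below ``tol`` or after ``max_iter`` rounds.
Each alternation weakly decreases the objective
J = sum_nj mu_nj^alpha d_nj^2.

Cluster-count selection uses Bezdek's partition entropy
H = -(1/L) sum_nj mu_nj ln(mu_nj), which is 0 for a crisp partition and
ln(c) for a maximally fuzzy one; the candidate c with minimum H wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InsufficientDataError, InvalidInputError, InvalidPartitionError
from .imaging import FeatureVectorSet

__all__ = [
    "FCMConfig",
    "FuzzyPartition",
    "fcm_fit",
    "partition_entropy",
    "partition_entropy_scan",
    "select_cluster_count",
]

logger = logging.getLogger(__name__)

_ROW_SUM_TOL = 1e-6


@dataclass(frozen=True)
class FCMConfig:
    """FCM hyperparameters.

    Defaults follow common practice for IHC texture partitions:
    alpha = 2, max_iter = 100, tol = 1e-5, and c = 20 clusters for
    full-size 150-pixel tiles (chosen near the partition-entropy
    optimum for such data).  ``seed`` fixes the random row-stochastic
    initial membership matrix, making fits bit-reproducible.
    """

    c: int = 20
    alpha: float = 2.0
    max_iter: int = 100
    tol: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c < 2:
            raise InvalidInputError(f"cluster count c must be >= 2, got {self.c}")
        if self.alpha <= 1.0:
            raise InvalidInputError(f"alpha must be > 1, got {self.alpha}")
        if self.max_iter < 1:
            raise InvalidInputError("max_iter must be >= 1")
        if self.tol <= 0:
            raise InvalidInputError("tol must be positive")


@dataclass
class FuzzyPartition:
    """Result of an FCM fit.

    Attributes
    ----------
    U
        L x c membership matrix, rows summing to 1.
    V
        c x K cluster-center matrix.
    H
        Partition entropy of U (natural log), in [0, ln c].
    n_iter
        Number of membership updates performed.
    converged
        Whether the membership change dropped below tolerance before
        the iteration cap.
    objective_history
        Objective J after each membership update; non-increasing.
    """

    U: np.ndarray
    V: np.ndarray
    H: float
    n_iter: int
    converged: bool
    seed: int | None = None
    objective_history: list[float] = field(default_factory=list)


def _validate_row_stochastic(U: np.ndarray) -> np.ndarray:
    U = np.asarray(U, dtype=float)
    if U.ndim != 2:
        raise InvalidPartitionError("membership matrix must be 2-D")
    if np.any(U < -1e-12) or np.any(U > 1 + 1e-12):
        raise InvalidPartitionError("memberships must lie in [0, 1]")
    row_sums = U.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > _ROW_SUM_TOL):
        worst = float(np.max(np.abs(row_sums - 1.0)))
        raise InvalidPartitionError(
            f"membership rows must sum to 1 (max deviation {worst:.2e})"
        )
    return U


def _membership_update(D: np.ndarray, alpha: float) -> np.ndarray:
    """Membership update from an L x c distance matrix.

    A point coinciding with one or more centers (zero distance) gets a
    crisp membership split equally among the coincident centers.
    """
    power = 2.0 / (alpha - 1.0)
    zero_rows = np.any(D == 0.0, axis=1)
    D_safe = np.where(zero_rows[:, np.newaxis], 1.0, D)
    inv = D_safe ** (-power)
    U = inv / inv.sum(axis=1, keepdims=True)
    if np.any(zero_rows):
        hits = D[zero_rows] == 0.0
        U[zero_rows] = hits / hits.sum(axis=1, keepdims=True)
    return U


def fcm_fit(X: FeatureVectorSet | np.ndarray, cfg: FCMConfig) -> FuzzyPartition:
    """Fit fuzzy c-means to a feature matrix.

    Parameters
    ----------
    X
        FeatureVectorSet or plain (L, K) array, L > c, finite entries.
    cfg
        Hyperparameters; ``cfg.seed`` determines the random initial
        membership matrix, so identical inputs give identical output.

    Raises
    ------
    InsufficientDataError
        If L <= c.
    InvalidInputError
        If any feature is non-finite.
    """
    data = X.vectors if isinstance(X, FeatureVectorSet) else np.asarray(X, dtype=float)
    if data.ndim != 2:
        raise InvalidInputError("feature matrix must be 2-D")
    if not np.all(np.isfinite(data)):
        raise InvalidInputError("features must be finite (no NaN/inf)")
    L = data.shape[0]
    if L <= cfg.c:
        raise InsufficientDataError(
            f"need more data points than clusters: L={L}, c={cfg.c}"
        )

    rng = np.random.default_rng(cfg.seed)
    U = rng.random((L, cfg.c))
    U /= U.sum(axis=1, keepdims=True)

    converged = False
    n_iter = 0
    history: list[float] = []
    for _ in range(cfg.max_iter):
        Um = U**cfg.alpha
        V = (Um.T @ data) / Um.sum(axis=0)[:, np.newaxis]
        D = cdist(data, V)
        U_new = _membership_update(D, cfg.alpha)
        n_iter += 1
        history.append(float(np.sum((U_new**cfg.alpha) * D**2)))
        delta = float(np.linalg.norm(U_new - U))
        U = U_new
        if delta < cfg.tol:
            converged = True
            break

    H = partition_entropy(U)
    return FuzzyPartition(
        U=U,
        V=V,
        H=H,
        n_iter=n_iter,
        converged=converged,
        seed=cfg.seed,
        objective_history=history,
    )


def partition_entropy(U: np.ndarray) -> float:
    """Bezdek partition entropy of a row-stochastic membership matrix.

    H = -(1/L) sum_j sum_n mu_nj ln(mu_nj), with 0 * ln 0 taken as 0.
    H = 0 for crisp partitions, ln(c) when every membership is 1/c.

    Raises
    ------
    InvalidPartitionError
        If any row sum deviates from 1 by more than 1e-6.
    """
    U = _validate_row_stochastic(U)
    L = U.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(U > 0.0, U * np.log(U), 0.0)
    return float(-terms.sum() / L) + 0.0  # avoid -0.0 for crisp partitions


def partition_entropy_scan(
    X: FeatureVectorSet | np.ndarray,
    c_min: int,
    c_max: int,
    cfg: FCMConfig | None = None,
) -> list[tuple[int, float]]:
    """Fit FCM for each c in [c_min, c_max] and return the (c, H) pairs."""
    cfg = cfg or FCMConfig()
    pairs = []
    for c in range(c_min, c_max + 1):
        part = fcm_fit(X, FCMConfig(c=c, alpha=cfg.alpha, max_iter=cfg.max_iter,
                                    tol=cfg.tol, seed=cfg.seed))
        logger.info("partition entropy scan: c=%d H=%.6f", c, part.H)
        pairs.append((c, part.H))
    return pairs


def select_cluster_count(
    X: FeatureVectorSet | np.ndarray,
    c_min: int,
    c_max: int,
    cfg: FCMConfig | None = None,
) -> int:
    """Cluster count minimising the partition entropy over [c_min, c_max].

    Ties are broken toward the smaller c.  All (c, H) pairs are logged
    at INFO level.
    """
    if not 2 <= c_min <= c_max:
        raise InvalidInputError(
            f"need 2 <= c_min <= c_max, got [{c_min}, {c_max}]"
        )
    pairs = partition_entropy_scan(X, c_min, c_max, cfg)
    best_c, _ = min(pairs, key=lambda p: (p[1], p[0]))
    return best_c


# ---------------------------------------------------------------------------
# serialization


def write_partition_csv(part: FuzzyPartition, u_path, v_path) -> None:
    """Write a partition as a two-file CSV pair (U matrix; V + metadata)."""
    np.savetxt(u_path, part.U, delimiter=",")
    with open(v_path, "w") as fh:
        fh.write(
            f"# H={part.H!r} n_iter={part.n_iter} converged={part.converged} "
            f"seed={part.seed}\n"
        )
        np.savetxt(fh, part.V, delimiter=",")
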