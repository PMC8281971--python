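"""k-nearest-neighbor Gaussian graphs and local weighted means (LWM).

The classifier ties every instance ``x_i`` to its *local weighted mean*

    x_hat_i = sum_{x_j in Ne(x_i)} W_ij x_j / sum_{x_j in Ne(x_i)} W_ij,

where ``Ne(x_i)`` holds the ``k`` nearest neighbors of ``x_i`` (Euclidean
distance, self excluded) and ``W_ij = exp(-gamma * ||x_i - x_j||^2)``.
``gamma`` controls the local scope of the Gaussian weighting: larger
``gamma`` means a narrower neighborhood influence.

In a reproducing-kernel feature space the same averaging applies to the
mapped points, so the Gram matrix between data and LWMs is obtained from
the plain Gram matrix by column-wise convex combination with the
normalized neighbor weights (``lwm_gram``); no explicit feature map is
ever required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InvalidInputError, InvalidParameterError


def _as_matrix(X, name: str = "X") -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise InvalidInputError(f"{name} must be 2-D, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise InvalidInputError(f"{name} contains non-finite entries")
    return X


def mean_pairwise_distance(X) -> float:
    """Mean Euclidean distance over all ordered pairs i != j.

    This is the statistic behind every "auto" width in the package.
    """
    X = _as_matrix(X)
    n = X.shape[0]
    if n < 2:
        raise InvalidInputError("need at least 2 instances for a pairwise distance")
    D = cdist(X, X)
    return float(D.sum() / (n * (n - 1)))


def resolve_gamma(X, gamma) -> float:
    """Resolve a Gaussian width: a positive number, or "auto" -> 1/(2*sigma^2)
    with sigma the mean pairwise Euclidean distance."""
    if isinstance(gamma, str):
        if gamma != "auto":
            raise InvalidParameterError(f"gamma must be positive or 'auto', got {gamma!r}")
        sigma = mean_pairwise_distance(X)
        if sigma == 0.0:
            raise InvalidInputError("all instances identical; cannot auto-resolve gamma")
        return 1.0 / (2.0 * sigma**2)
    gamma = float(gamma)
    if gamma <= 0:
        raise InvalidParameterError(f"gamma must be > 0, got {gamma}")
    return gamma


@dataclass
class NeighborGraph:
    """k-NN graph with Gaussian weights.

    Attributes
    ----------
    k : int
        Requested neighbor count; each row of ``neighbors`` has
        ``min(k, n-1)`` entries.
    gamma : float
        Resolved Gaussian width (> 0).
    neighbors : ndarray of int, shape (n, k_eff)
        Row i lists Ne(x_i), nearest first; self excluded, distance ties
        broken by lowest instance index.
    weights : ndarray, shape (n, k_eff)
        ``W_ij = exp(-gamma * ||x_i - x_j||^2)`` aligned with ``neighbors``.
    """

    k: int
    gamma: float
    neighbors: np.ndarray
    weights: np.ndarray

    @property
    def n(self) -> int:
        return self.neighbors.shape[0]

    def weight_matrix(self) -> np.ndarray:
        """Dense n x n matrix with ``W[s, j] > 0`` iff ``x_s in Ne(x_j)``."""
        n = self.n
        W = np.zeros((n, n))
        for j in range(n):
            W[self.neighbors[j], j] = self.weights[j]
        return W

    def normalized_weight_matrix(self) -> np.ndarray:
        """Column-stochastic matrix N with column j the normalized weights of
        Ne(x_j); satisfies ``X_hat = N.T @ X`` and ``K_bar = K @ N``."""
        W = self.weight_matrix()
        return W / W.sum(axis=0, keepdims=True)


def _knn_from_distances(D: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Neighbor indices (nearest first, stable lowest-index ties) for each row
    of a distance matrix whose excluded entries are +inf."""
    order = np.argsort(D, axis=1, kind="stable")
    return order[:, :k]


def build_knn_graph(X, k: int, gamma="auto") -> NeighborGraph:
    """Build the k-NN Gaussian-weight graph over the rows of ``X``.

    Self-neighbors are excluded; distance ties are broken by lowest
    instance index so the graph is deterministic. Duplicate points are
    legal and receive weight exp(0) = 1.
    """
    X = _as_matrix(X)
    n = X.shape[0]
    if n < 2:
        raise InvalidInputError("need at least 2 instances to build a graph")
    if k <= 0:
        raise InvalidParameterError(f"k must be a positive integer, got {k}")
    if k > n - 1:
        raise InvalidParameterError(f"k={k} exceeds n-1={n - 1}")
    gamma = resolve_gamma(X, gamma)
    D2 = cdist(X, X, metric="sqeuclidean")
    D = np.sqrt(D2)
    np.fill_diagonal(D, np.inf)
    neighbors = _knn_from_distances(D, k)
    d2 = np.take_along_axis(D2, neighbors, axis=1)
    weights = np.exp(-gamma * d2)
    return NeighborGraph(k=k, gamma=gamma, neighbors=neighbors, weights=weights)


def compute_lwm(X, graph: NeighborGraph) -> np.ndarray:
    """Local weighted means: row i is the Gaussian-weighted average of
    ``X[Ne(x_i)]``. Each row lies in the convex hull of its neighbors."""
    X = _as_matrix(X)
    if X.shape[0] != graph.n:
        raise InvalidInputError(
            f"graph was built on {graph.n} instances, X has {X.shape[0]}"
        )
    denom = graph.weights.sum(axis=1, keepdims=True)
    if np.any(denom <= 0):
        raise InvalidInputError("empty or zero-weight neighbor set")
    Wn = graph.weights / denom
    return np.einsum("ik,ikd->id", Wn, X[graph.neighbors])


def lwm_gram(K, graph: NeighborGraph) -> np.ndarray:
    """Gram matrix between data points and LWMs in kernel space.

    ``K_bar[i, j] = sum_{s in Ne(x_j)} W_sj K[i, s] / sum_s W_sj``,
    i.e. ``K_bar = K @ N`` with N the column-normalized neighbor weights.
    Valid for any Mercer kernel because the feature-space LWM is the same
    convex combination of mapped neighbors.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[1] != graph.n:
        raise InvalidInputError(
            f"K has shape {K.shape}, expected (*, {graph.n}) to match the graph"
        )
    return K @ graph.normalized_weight_matrix()


def new_neighbor_weights(Xnew, Xtrain, k: int, gamma: float) -> np.ndarray:
    """Column-stochastic (n_train x n_new) matrix of normalized Gaussian
    weights from each new point to its k nearest *training* instances.

    Training points at distance exactly zero from a new point are excluded,
    so evaluating a training point through this path reproduces the training
    graph's self-exclusion. If every training point coincides with the new
    point the point itself is its own LWM (uniform weights over duplicates).
    """
    Xnew = _as_matrix(Xnew, "Xnew")
    Xtrain = _as_matrix(Xtrain, "Xtrain")
    if Xnew.shape[1] != Xtrain.shape[1]:
        raise InvalidInputError(
            f"feature dimension mismatch: new {Xnew.shape[1]} vs train {Xtrain.shape[1]}"
        )
    n_train = Xtrain.shape[0]
    k = min(k, n_train)
    D2 = cdist(Xnew, Xtrain, metric="sqeuclidean")
    D = np.sqrt(D2)
    Dm = np.where(D == 0.0, np.inf, D)
    all_dup = np.isinf(Dm).all(axis=1)
    Dm[all_dup] = D[all_dup]  # degenerate: the point is its own LWM
    neighbors = _knn_from_distances(Dm, k)
    usable = np.isfinite(np.take_along_axis(Dm, neighbors, axis=1))
    d2 = np.take_along_axis(D2, neighbors, axis=1)
    w = np.exp(-gamma * d2) * usable
    N = np.zeros((n_train, Xnew.shape[0]))
    for j in range(Xnew.shape[0]):
        keep = w[j] > 0
        N[neighbors[j, keep], j] = w[j, keep] / w[j, keep].sum()
    return N


def lwm_for_new(Xnew, Xtrain, k: int, gamma: float) -> np.ndarray:
    """Input-space LWMs of new points over their nearest training instances."""
    N = new_neighbor_weights(Xnew, Xtrain, k, gamma)
    return N.T @ _as_matrix(Xtrain, "Xtrain")
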