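"""Possibilistic clustering-promoting semi-supervised kernel classifier.

The model learns, from a few labeled and many unlabeled instances, a pair
of mutually verifying predictors:

* a decision function ``f(x) = sum_i alpha_i K(x_i, x)`` with M outputs
  (one per class, targets are one-hot class codes ``c_m``), and
* a possibilistic label-membership function
  ``w_m(x) = exp(-(||f(x) - c_m||^2 + lambda_s ||f(x_hat) - c_m||^2) / (2C))``

where ``x_hat`` is the instance's local weighted mean (LWM). Memberships
live in (0, 1] per class and are *not* constrained to sum to one, so an
outlier far from every class receives low membership everywhere instead
of being forced into some class.

Training minimizes, by alternating exact coordinate updates,

    sum_labeled ||f(x_i) - y_i||^2  +  lambda_s sum_labeled ||f(x_hat_i) - y_i||^2
    + sum_m sum_unlabeled w_m(x_j)^2 ||f(x_j) - c_m||^2
    + lambda_s sum_m sum_unlabeled w_m(x_j)^2 ||f(x_hat_j) - c_m||^2
    + lambda ||f||_H^2
    + C sum_m sum_unlabeled (w_m^2 ln w_m^2 - w_m^2)        (fuzzy entropy)

subject to 0 <= w_m <= 1, with labeled memberships pinned one-hot. Both
updates are closed-form: for fixed memberships the objective decouples
across the M output coordinates into one symmetric linear system; for
fixed f each membership has the exponential solution above. The
alternation never increases the objective, which is bounded below, so the
objective trace converges; the loop stops on a relative-change test
|F_t - F_{t-1}| < epsilon |F_{t-1}|.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import (
    InvalidInputError,
    InvalidParameterError,
    NumericalError,
)
from .graph import (
    NeighborGraph,
    _as_matrix,
    build_knn_graph,
    lwm_gram,
    new_neighbor_weights,
    resolve_gamma,
)
from .kernels import KernelConfig, c_heuristic, gram, validate_precomputed

logger = logging.getLogger("pcper")

UNLABELED = -1


# ---------------------------------------------------------------------------
# labels


@dataclass
class LabelSet:
    """Semi-supervised label vector.

    ``codes[i]`` is the class code in {0, ..., M-1} for labeled instances
    and -1 for unlabeled ones. Every class must have at least one labeled
    instance.
    """

    codes: np.ndarray
    M: int

    def __post_init__(self):
        codes = np.asarray(self.codes, dtype=int)
        if codes.ndim != 1:
            raise InvalidInputError("label codes must be a 1-D integer vector")
        if self.M < 2:
            raise InvalidInputError(f"need at least 2 classes, got M={self.M}")
        if codes.size and (codes.min() < UNLABELED or codes.max() >= self.M):
            raise InvalidInputError(
                f"label codes must lie in {{-1, 0, ..., {self.M - 1}}}"
            )
        for m in range(self.M):
            if not np.any(codes == m):
                raise InvalidInputError(f"class {m} has no labeled instance")
        self.codes = codes

    @classmethod
    def from_codes(cls, codes, M: int | None = None) -> "LabelSet":
        codes = np.asarray(codes, dtype=int)
        if M is None:
            if not np.any(codes >= 0):
                raise InvalidInputError("no labeled instances to infer M from")
            M = int(codes.max()) + 1
        return cls(codes, M)

    @property
    def n(self) -> int:
        return self.codes.size

    @property
    def labeled_mask(self) -> np.ndarray:
        return self.codes != UNLABELED

    @property
    def labeled_idx(self) -> np.ndarray:
        return np.flatnonzero(self.codes != UNLABELED)

    @property
    def unlabeled_idx(self) -> np.ndarray:
        return np.flatnonzero(self.codes == UNLABELED)

    @property
    def n_labeled(self) -> int:
        return int(self.labeled_mask.sum())

    @property
    def n_unlabeled(self) -> int:
        return self.n - self.n_labeled

    def onehot_labeled(self) -> np.ndarray:
        """M x l one-hot targets Y_l over the labeled instances."""
        lab = self.labeled_idx
        Y = np.zeros((self.M, lab.size))
        Y[self.codes[lab], np.arange(lab.size)] = 1.0
        return Y


def init_labeled_membership(labels: LabelSet) -> tuple[np.ndarray, np.ndarray]:
    """Initial memberships: (V_unlabeled, fixed labeled block).

    Labeled instances get membership 1 in their own class and 0 elsewhere,
    held fixed for the whole fit. Unlabeled memberships start at zero so
    the first decision-function update fits the labeled data only.
    """
    V = np.zeros((labels.M, labels.n_unlabeled))
    return V, labels.onehot_labeled()


# ---------------------------------------------------------------------------
# Gram pair


@dataclass
class GramPair:
    """Training Gram matrix K and data-vs-LWM Gram matrix K_bar (both n x n)."""

    K: np.ndarray
    K_bar: np.ndarray

    def __post_init__(self):
        K = np.asarray(self.K, dtype=float)
        Kb = np.asarray(self.K_bar, dtype=float)
        if K.shape != Kb.shape or K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise InvalidInputError(
                f"K and K_bar must be equal square matrices, got {K.shape}, {Kb.shape}"
            )
        self.K, self.K_bar = K, Kb

    @property
    def n(self) -> int:
        return self.K.shape[0]

    @classmethod
    def from_graph(cls, K, graph: NeighborGraph) -> "GramPair":
        return cls(np.asarray(K, dtype=float), lwm_gram(K, graph))


# ---------------------------------------------------------------------------
# closed-form updates


def _code_sq_distances(F: np.ndarray) -> np.ndarray:
    """D[m, j] = ||F[:, j] - c_m||^2 for one-hot codes c_m (columns of I)."""
    sq = (F**2).sum(axis=0)
    return sq[None, :] - 2.0 * F + 1.0


def _weights_and_targets(labels: LabelSet, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-instance loss weights d and M x n target matrix T.

    Labeled: weight 1, one-hot target. Unlabeled j: weight sum_m w_m^2 and
    target column w_m^2 (the unnormalized quadratic expansion of the
    membership-weighted squared losses).
    """
    n, M = labels.n, labels.M
    d = np.ones(n)
    T = np.zeros((M, n))
    lab, unl = labels.labeled_idx, labels.unlabeled_idx
    T[:, lab] = labels.onehot_labeled()
    W2 = V**2
    d[unl] = W2.sum(axis=0)
    T[:, unl] = W2
    return d, T


def _system(gp: GramPair, labels: LabelSet, V, lam, lam_s):
    d, T = _weights_and_targets(labels, np.asarray(V, dtype=float))
    K, Kb = gp.K, gp.K_bar
    A = (K * d) @ K + lam_s * (Kb * d) @ Kb.T + lam * K
    Bm = T @ (K + lam_s * Kb.T)
    return A, Bm


def solve_decision(gp: GramPair, labels: LabelSet, V, lam: float, lam_s: float) -> np.ndarray:
    """Exact minimizer of the decision-function subproblem for fixed memberships.

    The M-output objective decouples per output coordinate into a weighted
    regularized least-squares problem; all coordinates share the symmetric
    system matrix ``A = K D K + lambda_s K_bar D K_bar^T + lambda K``, so a
    single n x n solve with M right-hand sides yields the dual coefficients
    alpha (M x n). If the direct solve fails, a jitter of
    ``1e-10 * trace(K)/n`` is added to the diagonal and finally a
    least-squares solve is used (with a warning).
    """
    if lam <= 0:
        raise InvalidParameterError(f"lambda must be > 0, got {lam}")
    if lam_s < 0:
        raise InvalidParameterError(f"lambda_s must be >= 0, got {lam_s}")
    V = np.asarray(V, dtype=float)
    if V.shape != (labels.M, labels.n_unlabeled):
        raise InvalidInputError(
            f"V has shape {V.shape}, expected ({labels.M}, {labels.n_unlabeled})"
        )
    if np.any((V < 0) | (V > 1)):
        raise InvalidInputError("memberships must lie in [0, 1]")
    if gp.n != labels.n:
        raise InvalidInputError("Gram matrices inconsistent with label vector length")
    A, Bm = _system(gp, labels, V, lam, lam_s)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", scipy.linalg.LinAlgWarning)
            alpha = scipy.linalg.solve(A, Bm.T, assume_a="sym").T
        if np.all(np.isfinite(alpha)):
            return np.ascontiguousarray(alpha)
    except (scipy.linalg.LinAlgError, scipy.linalg.LinAlgWarning, ValueError):
        pass
    jitter = 1e-10 * np.trace(gp.K) / gp.n
    logger.warning("decision solve ill-conditioned; adding jitter %.3e", jitter)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", scipy.linalg.LinAlgWarning)
            alpha = scipy.linalg.solve(
                A + jitter * np.eye(gp.n), Bm.T, assume_a="sym"
            ).T
        if np.all(np.isfinite(alpha)):
            return np.ascontiguousarray(alpha)
    except (scipy.linalg.LinAlgError, ValueError):
        pass
    logger.warning("falling back to least-squares decision solve")
    alpha, *_ = np.linalg.lstsq(A, Bm.T, rcond=None)
    alpha = alpha.T
    if not np.all(np.isfinite(alpha)):
        raise NumericalError("decision-function solve produced non-finite coefficients")
    return np.ascontiguousarray(alpha)


def decision_gradient(alpha, gp: GramPair, labels: LabelSet, V, lam, lam_s) -> np.ndarray:
    """Gradient of the fixed-membership objective at ``alpha`` (M x n)."""
    A, Bm = _system(gp, labels, V, lam, lam_s)
    return 2.0 * (alpha @ A - Bm)


def update_membership(f_X, f_LWM, C: float, lambda_s: float) -> np.ndarray:
    """Closed-form possibilistic membership update.

    ``w_m(x) = exp(-(||f(x) - c_m||^2 + lambda_s ||f(x_hat) - c_m||^2)/(2C))``,
    the exact stationary point of the membership subproblem (and its global
    minimum on [0, 1]). Inputs are M x n arrays of decision values at the
    points and at their LWMs. Exponent underflow clamps to 0.
    """
    if C <= 0:
        raise InvalidParameterError(f"C must be > 0, got {C}")
    f_X = np.atleast_2d(np.asarray(f_X, dtype=float))
    f_LWM = np.atleast_2d(np.asarray(f_LWM, dtype=float))
    if f_X.shape != f_LWM.shape:
        raise InvalidInputError("f(x) and f(x_hat) arrays must have equal shapes")
    d = _code_sq_distances(f_X) + lambda_s * _code_sq_distances(f_LWM)
    with np.errstate(under="ignore"):
        return np.exp(-d / (2.0 * C))


def objective(alpha, V, gp: GramPair, labels: LabelSet, lam, lam_s, C) -> float:
    """Full training objective (all six terms, membership exponent 2).

    The fuzzy-entropy term uses the convention 0*ln 0 = 0, so the all-zero
    initialization is finite. Note the entropy term is <= 0, so the
    objective itself may be negative; it is bounded below by -C*M*u.
    """
    alpha = np.asarray(alpha, dtype=float)
    V = np.asarray(V, dtype=float)
    K, Kb = gp.K, gp.K_bar
    G = alpha @ K
    Gb = alpha @ Kb
    lab, unl = labels.labeled_idx, labels.unlabeled_idx
    Y = labels.onehot_labeled()
    t1 = float(((G[:, lab] - Y) ** 2).sum())
    t2 = float(((Gb[:, lab] - Y) ** 2).sum())
    W2 = V**2
    t3 = float((W2 * _code_sq_distances(G[:, unl])).sum())
    t4 = float((W2 * _code_sq_distances(Gb[:, unl])).sum())
    t5 = float(lam * (alpha * G).sum())  # lam * tr(alpha K alpha^T)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = np.where(W2 > 0, W2 * np.log(W2), 0.0) - W2
    t6 = float(C * ent.sum())
    return t1 + lam_s * t2 + t3 + lam_s * t4 + t5 + t6


# ---------------------------------------------------------------------------
# hyper-parameters and fitted model


@dataclass
class Hyperparams:
    """Tunable parameters of the fit.

    Defaults follow the heuristics that work across the EEG-style
    benchmarks: small ridge and consistency weights, 5 neighbors, entropy
    weight C set from the data's divergence (mean distance to centroid).
    """

    lambda_: float = 0.1
    lambda_s: float = 0.1
    C: float | str = "auto"
    k: int = 5
    gamma: float | str = "auto"
    epsilon: float = 1e-3
    max_iter: int = 50
    init: str = "zeros"  # or "random"

    @classmethod
    def preset(cls, name: str) -> "Hyperparams":
        """Named presets: "default" (lambda=0.1) and "deap" (lambda=1)."""
        if name == "default":
            return cls()
        if name == "deap":
            return cls(lambda_=1.0)
        raise InvalidParameterError(f"unknown preset {name!r}")

    def validate(self) -> None:
        if self.lambda_ <= 0:
            raise InvalidParameterError(f"lambda must be > 0, got {self.lambda_}")
        if self.lambda_s < 0:
            raise InvalidParameterError(f"lambda_s must be >= 0, got {self.lambda_s}")
        if not isinstance(self.C, str) and self.C <= 0:
            raise InvalidParameterError(f"C must be > 0 or 'auto', got {self.C}")
        if self.k <= 0:
            raise InvalidParameterError(f"k must be positive, got {self.k}")
        if self.epsilon <= 0:
            raise InvalidParameterError(f"epsilon must be > 0, got {self.epsilon}")
        if self.max_iter < 0:
            raise InvalidParameterError(f"max_iter must be >= 0, got {self.max_iter}")
        if self.init not in ("zeros", "random"):
            raise InvalidParameterError(f"init must be 'zeros' or 'random', got {self.init}")


@dataclass
class PCPModel:
    """A fitted classifier: dual coefficients plus everything needed to
    reproduce predictions (training data, kernel and graph configuration,
    resolved hyper-parameters, objective trace)."""

    alpha: np.ndarray  # M x n
    kernel: KernelConfig  # widths resolved
    labels: LabelSet
    hyper: Hyperparams  # C and gamma resolved to numbers
    Xtrain: np.ndarray | None  # None for precomputed kernels
    Ktrain: np.ndarray
    K_bar: np.ndarray
    graph: NeighborGraph
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = False
    hard: bool = False

    @property
    def M(self) -> int:
        return self.labels.M

    @property
    def gram_pair(self) -> GramPair:
        return GramPair(self.Ktrain, self.K_bar)


def _kernel_sq_distances(K: np.ndarray) -> np.ndarray:
    """Feature-space squared distances ||phi_i - phi_j||^2 from a Gram matrix."""
    dg = np.diag(K)
    D2 = dg[:, None] + dg[None, :] - 2.0 * K
    np.fill_diagonal(D2, 0.0)
    return np.clip(D2, 0.0, None)


def _graph_from_gram(K: np.ndarray, k: int, gamma) -> NeighborGraph:
    """k-NN graph in the kernel feature space (for precomputed kernels)."""
    from .graph import _knn_from_distances

    n = K.shape[0]
    if k > n - 1:
        raise InvalidParameterError(f"k={k} exceeds n-1={n - 1}")
    D2 = _kernel_sq_distances(K)
    D = np.sqrt(D2)
    if isinstance(gamma, str):
        if gamma != "auto":
            raise InvalidParameterError(f"gamma must be positive or 'auto', got {gamma!r}")
        sigma = float(D.sum() / (n * (n - 1)))
        if sigma == 0:
            raise InvalidInputError("all instances identical in feature space")
        gamma = 1.0 / (2.0 * sigma**2)
    Dm = D.copy()
    np.fill_diagonal(Dm, np.inf)
    neighbors = _knn_from_distances(Dm, k)
    d2 = np.take_along_axis(D2, neighbors, axis=1)
    return NeighborGraph(k=k, gamma=float(gamma), neighbors=neighbors, weights=np.exp(-gamma * d2))


def _prepare(X, labels: LabelSet, hyper: Hyperparams, kernel: KernelConfig):
    """Resolve widths/C, build graph and Gram pair. Returns
    (Xtrain_or_None, resolved_kernel, resolved_hyper, graph, GramPair)."""
    hyper.validate()
    if labels.n_unlabeled == 0:
        raise InvalidInputError("no unlabeled instances; the fit is semi-supervised")
    if kernel.name == "precomputed":
        K = validate_precomputed(X)
        if K.shape[0] != labels.n:
            raise InvalidInputError("Gram size does not match label vector")
        graph = _graph_from_gram(K, hyper.k, hyper.gamma)
        Xtrain = None
        C = hyper.C
        if isinstance(C, str):
            # divergence in feature space: mean distance to the centroid
            n = K.shape[0]
            dg = np.diag(K)
            d2 = dg - 2.0 * K.mean(axis=1) + K.mean()
            C = float(np.sqrt(np.clip(d2, 0, None)).mean())
        kernel_res = kernel
    else:
        Xtrain = _as_matrix(X)
        if Xtrain.shape[0] != labels.n:
            raise InvalidInputError(
                f"{Xtrain.shape[0]} instances but {labels.n} labels"
            )
        kernel_res = kernel.resolve(Xtrain)
        gamma = resolve_gamma(Xtrain, hyper.gamma)
        graph = build_knn_graph(Xtrain, hyper.k, gamma)
        K = gram(Xtrain, Xtrain, kernel_res)
        C = c_heuristic(Xtrain) if isinstance(hyper.C, str) else float(hyper.C)
    if C == 0:
        raise InvalidInputError(
            "data divergence C resolved to 0 (all instances identical)"
        )
    hyper_res = Hyperparams(
        lambda_=hyper.lambda_,
        lambda_s=hyper.lambda_s,
        C=float(C),
        k=hyper.k,
        gamma=float(graph.gamma),
        epsilon=hyper.epsilon,
        max_iter=hyper.max_iter,
        init=hyper.init,
    )
    return Xtrain, kernel_res, hyper_res, graph, GramPair.from_graph(K, graph)


def _alternate(gp, labels, hyper, update_fn, rng=None):
    """Shared alternating loop for the soft and hard variants.

    ``update_fn(G_unl, Gb_unl) -> (V, C_for_objective)`` produces the
    membership (or one-hot assignment) matrix from decision values on the
    unlabeled instances and their LWMs.
    """
    lam, lam_s = hyper.lambda_, hyper.lambda_s
    V = np.zeros((labels.M, labels.n_unlabeled))
    if hyper.init == "random":
        rng = np.random.default_rng(rng)
        V = rng.uniform(size=V.shape)
    alpha = solve_decision(gp, labels, V, lam, lam_s)
    trace: list[float] = []
    converged = False
    unl = labels.unlabeled_idx
    for it in range(hyper.max_iter):
        G = alpha @ gp.K
        Gb = alpha @ gp.K_bar
        V, C_obj = update_fn(G[:, unl], Gb[:, unl])
        alpha = solve_decision(gp, labels, V, lam, lam_s)
        F = objective(alpha, V, gp, labels, lam, lam_s, C_obj)
        if not np.isfinite(F):
            raise NumericalError(f"objective became non-finite at iteration {it + 1}")
        trace.append(F)
        if len(trace) >= 2:
            Fp = trace[-2]
            rel = abs(F - Fp) / abs(Fp) if Fp != 0 else np.inf
            logger.info("iter %d: F=%.6g rel_change=%.3g", it + 1, F, rel)
            if abs(F) < 1e-12 or abs(F - Fp) < hyper.epsilon * abs(Fp):
                converged = True
                break
        else:
            logger.info("iter 1: F=%.6g", F)
    return alpha, V, trace, converged


def fit(X, labels: LabelSet, hyper: Hyperparams | None = None,
        kernel: KernelConfig | None = None, rng=None) -> PCPModel:
    """Fit the possibilistic classifier by alternating closed-form updates.

    Starts from the labeled data only (zero unlabeled memberships), then
    alternates the membership update and the decision solve until the
    relative objective change falls below ``epsilon`` or ``max_iter``
    alternations. With ``max_iter=0`` the model is the labeled-only
    initialization (pure kernel ridge on the labels when ``lambda_s=0``).
    """
    hyper = hyper or Hyperparams()
    kernel = kernel or KernelConfig("rbf")
    Xtrain, kcfg, hyp, graph, gp = _prepare(X, labels, hyper, kernel)
    C, lam_s = hyp.C, hyp.lambda_s

    def update(G_unl, Gb_unl):
        return update_membership(G_unl, Gb_unl, C, lam_s), C

    alpha, V, trace, converged = _alternate(gp, labels, hyp, update, rng=rng)
    return PCPModel(
        alpha=alpha, kernel=kcfg, labels=labels, hyper=hyp, Xtrain=Xtrain,
        Ktrain=gp.K, K_bar=gp.K_bar, graph=graph,
        objective_trace=trace, converged=converged, hard=False,
    )


# ---------------------------------------------------------------------------
# prediction


def _cross_grams(model: PCPModel, Xnew):
    """(K(train, new), K(train, new LWMs)) as n_train x n_new arrays.

    ``Xnew=None`` means the training set itself (the transductive path, and
    the only path available for precomputed kernels).
    """
    if Xnew is None:
        return model.Ktrain, model.K_bar
    if model.kernel.name == "precomputed":
        Kx = np.asarray(Xnew, dtype=float).T  # user passes (n_new, n_train)
        if Kx.shape[0] != model.labels.n:
            raise InvalidInputError(
                "for precomputed kernels pass the (n_new, n_train) cross-Gram"
            )
        raise InvalidInputError(
            "LWM-based prediction for precomputed kernels is only available "
            "on the training set (pass Xnew=None)"
        )
    Xnew = _as_matrix(Xnew, "Xnew")
    if Xnew.shape[1] != model.Xtrain.shape[1]:
        raise InvalidInputError(
            f"feature dimension mismatch: {Xnew.shape[1]} vs {model.Xtrain.shape[1]}"
        )
    Kx = gram(model.Xtrain, Xnew, model.kernel)
    N = new_neighbor_weights(Xnew, model.Xtrain, model.hyper.k, model.hyper.gamma)
    return Kx, model.Ktrain @ N


def decision_values(model: PCPModel, Xnew=None) -> np.ndarray:
    """Decision function ``f`` at new points: (n_new, M) array of per-class
    scores ``f_m(x) = sum_i alpha_{m,i} K(x_i, x)``.

    For precomputed-kernel models pass the (n_new, n_train) cross-Gram
    instead of features, or ``None`` for the training set.
    """
    if Xnew is not None and model.kernel.name == "precomputed":
        Kx = np.asarray(Xnew, dtype=float).T
        if Kx.shape[0] != model.labels.n:
            raise InvalidInputError(
                "for precomputed kernels pass the (n_new, n_train) cross-Gram"
            )
        return (model.alpha @ Kx).T
    Kx, _ = _cross_grams(model, Xnew)
    return (model.alpha @ Kx).T


def membership_values(model: PCPModel, Xnew=None) -> np.ndarray:
    """Possibilistic memberships at new points: (n_new, M) array in (0, 1].

    Each point's LWM is formed from its k nearest training instances with
    the training gamma, and the closed-form membership formula is applied
    with the model's C and lambda_s.
    """
    Kx, Kb = _cross_grams(model, Xnew)
    fX = model.alpha @ Kx
    fL = model.alpha @ Kb
    return update_membership(fX, fL, model.hyper.C, model.hyper.lambda_s).T


def predict(model: PCPModel, Xnew=None, by: str = "decision") -> np.ndarray:
    """Predicted class codes by argmax of the chosen score; ties break to
    the lowest class code."""
    if by == "decision":
        scores = decision_values(model, Xnew)
    elif by == "membership":
        scores = membership_values(model, Xnew)
    else:
        raise InvalidParameterError(f"by must be 'decision' or 'membership', got {by!r}")
    return np.argmax(scores, axis=1)


# ---------------------------------------------------------------------------
# consistency diagnostics

INTRINSIC = "intrinsic"
FAKE_CONSISTENT = "fake_consistent"
INCONSISTENT = "inconsistent"


@dataclass
class ConsistencyReport:
    """Per-instance agreement diagnosis between the decision function and
    the membership function.

    An instance is *intrinsic* when its point and its LWM share the same
    decision-function argmax; *fake-consistent* when they do not but the
    margin inequality ``f_j(x_hat) - f_m(x_hat) < (f_m(x) - f_j(x)) / lambda_s``
    holds for every competitor j (the two predictors still agree);
    otherwise *inconsistent* — a boundary instance whose prediction is
    unreliable.
    """

    categories: np.ndarray  # of {INTRINSIC, FAKE_CONSISTENT, INCONSISTENT}
    prediction_consistency_rate: float  # fraction argmax f == argmax w
    ground_truth_consistency_rate: float  # fraction intrinsic

    @property
    def counts(self) -> dict:
        return {
            c: int((self.categories == c).sum())
            for c in (INTRINSIC, FAKE_CONSISTENT, INCONSISTENT)
        }


def categorize_consistency(f_X, f_LWM, lambda_s: float) -> np.ndarray:
    """Categorize instances from their decision values at the points (M x n)
    and at their LWMs.

    *intrinsic* when argmax f(x) = argmax f(x_hat); else *fake_consistent*
    when, with m = argmax f(x), every competitor j satisfies
    ``f_j(x_hat) - f_m(x_hat) < (f_m(x) - f_j(x)) / lambda_s``; else
    *inconsistent*. With ``lambda_s = 0`` every instance is intrinsic by
    convention (the LWM term has no influence).
    """
    fX = np.atleast_2d(np.asarray(f_X, dtype=float))
    fL = np.atleast_2d(np.asarray(f_LWM, dtype=float))
    n = fX.shape[1]
    if lambda_s == 0:
        return np.full(n, INTRINSIC, dtype=object)
    pred_f = np.argmax(fX, axis=0)
    intrinsic = pred_f == np.argmax(fL, axis=0)
    fm_x = fX[pred_f, np.arange(n)]
    fm_l = fL[pred_f, np.arange(n)]
    lhs = fL - fm_l[None, :]
    rhs = (fm_x[None, :] - fX) / lambda_s
    ok = lhs < rhs
    ok[pred_f, np.arange(n)] = True
    fake = ~intrinsic & ok.all(axis=0)
    cats = np.full(n, INCONSISTENT, dtype=object)
    cats[fake] = FAKE_CONSISTENT
    cats[intrinsic] = INTRINSIC
    return cats


def classify_consistency(model: PCPModel, Xnew=None) -> ConsistencyReport:
    """Three-way diagnosis of each instance plus the two consistency rates.

    With ``lambda_s = 0`` the membership is a monotone transform of the
    decision values, so every instance is intrinsic by convention and the
    prediction consistency rate is exactly 1.
    """
    Kx, Kb = _cross_grams(model, Xnew)
    fX = model.alpha @ Kx
    fL = model.alpha @ Kb
    lam_s = model.hyper.lambda_s
    pred_f = np.argmax(fX, axis=0)
    w = update_membership(fX, fL, model.hyper.C, lam_s)
    pred_w = np.argmax(w, axis=0)
    prediction_rate = float(np.mean(pred_f == pred_w))
    cats = categorize_consistency(fX, fL, lam_s)
    return ConsistencyReport(
        cats, prediction_rate, float(np.mean(cats == INTRINSIC))
    )
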