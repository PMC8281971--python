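"""Hard-clustering ablation of the possibilistic classifier.

Instead of graded memberships, each unlabeled instance is assigned exactly
one one-hot pseudo-label per alternation:

    y_j = argmin_m ||f(x_j) - c_m||^2 + lambda_s ||f(x_hat_j) - c_m||^2,

the exact minimizer of the unlabeled loss terms for fixed f. The decision
solve is unchanged (one-hot assignments are memberships with values in
{0, 1}), the objective drops the entropy term, and the same alternation /
stopping rule applies. The hard variant serves as the robustness baseline:
an outlier must be claimed in full by some class, whereas the soft variant
can give it low membership everywhere.
"""

from __future__ import annotations

import numpy as np

from .core import (
    Hyperparams,
    LabelSet,
    PCPModel,
    _alternate,
    _code_sq_distances,
    _prepare,
)
from .errors import InvalidInputError
from .kernels import KernelConfig


def hard_assign(f_X, f_LWM, lambda_s: float) -> np.ndarray:
    """One-hot class assignment minimizing the joint point + LWM squared
    distance to the class codes. Ties break to the lowest class code.

    Inputs are M x n arrays of decision values; returns the integer code
    vector of length n. With ``lambda_s = 0`` this reduces to
    ``argmax_m f_m(x)`` for one-hot codes.
    """
    f_X = np.atleast_2d(np.asarray(f_X, dtype=float))
    f_LWM = np.atleast_2d(np.asarray(f_LWM, dtype=float))
    if f_X.shape != f_LWM.shape:
        raise InvalidInputError("f(x) and f(x_hat) arrays must have equal shapes")
    cost = _code_sq_distances(f_X) + lambda_s * _code_sq_distances(f_LWM)
    return np.argmin(cost, axis=0)


def _onehot(codes: np.ndarray, M: int) -> np.ndarray:
    V = np.zeros((M, codes.size))
    V[codes, np.arange(codes.size)] = 1.0
    return V


def fit_hard(X, labels: LabelSet, hyper: Hyperparams | None = None,
             kernel: KernelConfig | None = None, rng=None) -> PCPModel:
    """Fit the hard-clustering variant.

    Alternates the decision solve with the one-hot assignment, recording
    the entropy-free objective; the trace is non-increasing because both
    steps are exact coordinate minimizers. ``model.hard`` is True and the
    final assignment is recoverable as ``predict`` on the training set.
    """
    hyper = hyper or Hyperparams()
    kernel = kernel or KernelConfig("rbf")
    Xtrain, kcfg, hyp, graph, gp = _prepare(X, labels, hyper, kernel)
    lam_s = hyp.lambda_s
    M = labels.M

    def update(G_unl, Gb_unl):
        codes = hard_assign(G_unl, Gb_unl, lam_s)
        return _onehot(codes, M), 0.0  # C=0 removes the entropy term

    alpha, V, trace, converged = _alternate(gp, labels, hyp, update, rng=rng)
    return PCPModel(
        alpha=alpha, kernel=kcfg, labels=labels, hyper=hyp, Xtrain=Xtrain,
        Ktrain=gp.K, K_bar=gp.K_bar, graph=graph,
        objective_trace=trace, converged=converged, hard=True,
    )
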