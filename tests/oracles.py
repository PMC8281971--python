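"""Independent oracles used by the unit and acceptance tests.

Everything here is written directly from the method's defining formulas
(scalar loops or per-class numpy expressions plus generic numeric
optimization), deliberately avoiding the package's assembled linear
systems and vectorized shortcuts so the two routes can disagree if either
is wrong.
"""

import numpy as np
from scipy.optimize import minimize, minimize_scalar


def loop_decision_values(alpha, Kcols):
    """f_m(x_j) = sum_i alpha[m, i] * K[i, j], by scalar loops."""
    M, n = alpha.shape
    ncols = Kcols.shape[1]
    F = np.zeros((M, ncols))
    for m in range(M):
        for j in range(ncols):
            F[m, j] = sum(alpha[m, i] * Kcols[i, j] for i in range(n))
    return F


def loop_fixed_membership_objective(alpha, K, Kb, codes, M, V, lam, lam_s):
    """Decision-step objective (fixed memberships), term by term in scalar
    loops; slow but maximally transparent."""
    n = len(codes)
    total = 0.0
    ui = 0
    for j in range(n):
        fx = np.array([sum(alpha[m, i] * K[i, j] for i in range(n)) for m in range(M)])
        fl = np.array([sum(alpha[m, i] * Kb[i, j] for i in range(n)) for m in range(M)])
        if codes[j] >= 0:
            y = np.zeros(M)
            y[codes[j]] = 1.0
            total += np.sum((fx - y) ** 2) + lam_s * np.sum((fl - y) ** 2)
        else:
            for m in range(M):
                c = np.zeros(M)
                c[m] = 1.0
                w2 = V[m, ui] ** 2
                total += w2 * np.sum((fx - c) ** 2) + lam_s * w2 * np.sum((fl - c) ** 2)
            ui += 1
    for m in range(M):
        total += lam * sum(
            alpha[m, i] * K[i, j] * alpha[m, j] for i in range(n) for j in range(n)
        )
    return total


def fixed_membership_objective(alpha, K, Kb, codes, M, V, lam, lam_s):
    """Same objective written per class with numpy inner products (fast
    enough to drive a generic minimizer); still independent of the
    package's assembled normal-equation system."""
    n = len(codes)
    lab = np.flatnonzero(codes >= 0)
    unl = np.flatnonzero(codes < 0)
    F = alpha @ K
    Fb = alpha @ Kb
    total = 0.0
    Y = np.zeros((M, lab.size))
    Y[codes[lab], np.arange(lab.size)] = 1.0
    total += np.sum((F[:, lab] - Y) ** 2) + lam_s * np.sum((Fb[:, lab] - Y) ** 2)
    for m in range(M):
        c = np.zeros(M)
        c[m] = 1.0
        w2 = V[m] ** 2
        dx = ((F[:, unl] - c[:, None]) ** 2).sum(axis=0)
        dl = ((Fb[:, unl] - c[:, None]) ** 2).sum(axis=0)
        total += np.sum(w2 * dx) + lam_s * np.sum(w2 * dl)
    for m in range(M):
        total += lam * alpha[m] @ K @ alpha[m]
    return total


def loop_full_objective(alpha, K, Kb, codes, M, V, lam, lam_s, C):
    """Complete training objective including the fuzzy-entropy term."""
    total = loop_fixed_membership_objective(alpha, K, Kb, codes, M, V, lam, lam_s)
    for m in range(M):
        for j in range(V.shape[1]):
            w2 = V[m, j] ** 2
            if w2 > 0:
                total += C * (w2 * np.log(w2) - w2)
    return total


def numeric_decision_minimizer(K, Kb, codes, M, V, lam, lam_s, x0=None):
    """Generic numeric minimizer of the decision-step objective over alpha."""
    n = len(codes)

    def fun(a):
        return fixed_membership_objective(
            a.reshape(M, n), K, Kb, codes, M, V, lam, lam_s
        )

    if x0 is None:
        x0 = np.zeros(M * n)
    res = minimize(fun, x0, method="L-BFGS-B",
                   options={"maxiter": 5000, "maxfun": 200000,
                            "ftol": 1e-15, "gtol": 1e-12})
    return res.x.reshape(M, n), res.fun


def numeric_membership_minimizer(d1, d2, lam_s, C):
    """1-D numeric minimizer of the per-element membership objective
    w^2 d1 + lam_s w^2 d2 + C (w^2 ln w^2 - w^2) over w in [0, 1]."""

    def g(w):
        w2 = w * w
        ent = w2 * np.log(w2) - w2 if w2 > 0 else 0.0
        return w2 * d1 + lam_s * w2 * d2 + C * ent

    res = minimize_scalar(g, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-12})
    return res.x
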