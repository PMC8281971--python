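"""Synthetic semi-supervised classification problems.

Generates the statistical setting the classifier assumes: well-clustered
Gaussian classes, very few labels, many unlabeled instances, and
optionally a fraction of distant shell outliers mixed into the unlabeled
pool. Class centers sit at the vertices of a regular simplex scaled so
that neighboring centers are ``separation`` within-class standard
deviations apart — at the default separation of 8 the classes are
essentially non-overlapping, giving unambiguous ground truth. Outliers
are drawn uniformly on a sphere of radius ``outlier_scale`` times the
inlier data radius around the centroid, so every outlier is farther from
every class center than any inlier (checkable by construction).

All draws come from a single seeded generator in a documented order
(centers -> class points in class order -> label selection per class ->
outliers), so fixtures are stable across runs and versions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import UNLABELED, LabelSet
from .errors import InvalidInputError, InvalidParameterError


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic problem.

    ``separation`` is the center spacing in units of ``noise_sd``. Exactly
    one of ``n_labeled_per_class`` / ``n_labeled_total`` must be set; a
    total is distributed as evenly as possible, extra labels going to the
    lowest class codes (10 labels over 3 classes -> 4, 3, 3).
    """

    M: int = 3
    n_per_class: int = 100
    d: int = 2
    separation: float = 8.0
    noise_sd: float = 1.0
    outlier_fraction: float = 0.0
    outlier_scale: float = 5.0
    n_labeled_per_class: int | None = None
    n_labeled_total: int | None = 10
    seed: int = 0

    def validate(self) -> None:
        if self.M < 2:
            raise InvalidParameterError("need at least 2 classes")
        if self.n_per_class < 1 or self.d < 1:
            raise InvalidParameterError("counts and dimensions must be positive")
        if self.d < self.M - 1:
            raise InvalidParameterError(
                f"d={self.d} too small to place {self.M} simplex centers (need d >= M-1)"
            )
        if not (0 <= self.outlier_fraction < 1):
            raise InvalidParameterError("outlier_fraction must lie in [0, 1)")
        if self.noise_sd <= 0 or self.separation <= 0 or self.outlier_scale <= 0:
            raise InvalidParameterError("scales must be positive")
        if (self.n_labeled_per_class is None) == (self.n_labeled_total is None):
            raise InvalidParameterError(
                "set exactly one of n_labeled_per_class / n_labeled_total"
            )
        for count in self._labels_per_class():
            if count < 1:
                raise InvalidInputError("every class needs at least one label")
            if count > self.n_per_class:
                raise InvalidInputError(
                    "n_labeled_per_class exceeds n_per_class"
                )
        if sum(self._labels_per_class()) >= self.M * self.n_per_class:
            raise InvalidInputError("no unlabeled instances would remain")

    def _labels_per_class(self) -> list[int]:
        if self.n_labeled_per_class is not None:
            return [self.n_labeled_per_class] * self.M
        base, extra = divmod(self.n_labeled_total, self.M)
        return [base + (1 if m < extra else 0) for m in range(self.M)]


def _simplex_centers(M: int, d: int, edge: float) -> np.ndarray:
    """Vertices of a regular (M-1)-simplex with the given edge length,
    centered at the origin, embedded in R^d (d >= M-1)."""
    # Start from scaled standard basis vectors in R^M: |e_i - e_j| = sqrt(2)
    E = np.eye(M) * (edge / np.sqrt(2.0))
    E -= E.mean(axis=0)
    # The rows span an (M-1)-dim subspace; rotate into its coordinates
    _, _, Vt = np.linalg.svd(E, full_matrices=False)
    coords = E @ Vt.T[:, : M - 1]
    centers = np.zeros((M, d))
    centers[:, : M - 1] = coords
    return centers


def make_problem(spec: SyntheticSpec):
    """Generate one problem.

    Returns ``(X, labels, truth, outlier_mask)``: the feature matrix
    (inliers in class order, then outliers), the semi-supervised
    :class:`LabelSet` (-1 for unlabeled), the ground-truth codes (-1 for
    outliers, which belong to no class), and the boolean outlier mask.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    centers = _simplex_centers(spec.M, spec.d, spec.separation * spec.noise_sd)
    # small seeded random rotation so coordinate axes carry no special role
    Q, _ = np.linalg.qr(rng.standard_normal((spec.d, spec.d)))
    centers = centers @ Q.T

    X_in = np.vstack([
        centers[m] + spec.noise_sd * rng.standard_normal((spec.n_per_class, spec.d))
        for m in range(spec.M)
    ])
    truth_in = np.repeat(np.arange(spec.M), spec.n_per_class)

    codes = np.full(truth_in.size, UNLABELED, dtype=int)
    for m, n_lab in enumerate(spec._labels_per_class()):
        pool = np.flatnonzero(truth_in == m)
        chosen = rng.choice(pool, size=n_lab, replace=False)
        codes[chosen] = m

    n_out = int(np.ceil(spec.outlier_fraction * X_in.shape[0])) if spec.outlier_fraction > 0 else 0
    if n_out:
        centroid = X_in.mean(axis=0)
        radius = np.linalg.norm(X_in - centroid, axis=1).max()
        dirs = rng.standard_normal((n_out, spec.d))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        X_out = centroid + spec.outlier_scale * radius * dirs
        X = np.vstack([X_in, X_out])
        codes = np.concatenate([codes, np.full(n_out, UNLABELED)])
        truth = np.concatenate([truth_in, np.full(n_out, UNLABELED)])
        mask = np.concatenate([np.zeros(X_in.shape[0], bool), np.ones(n_out, bool)])
    else:
        X, truth, mask = X_in, truth_in, np.zeros(X_in.shape[0], bool)

    return X, LabelSet(codes, spec.M), truth, mask


def split_report(labels: LabelSet) -> dict:
    """Bookkeeping summary: labeled/unlabeled counts and per-class labeled
    counts (used by the CLI log)."""
    per_class = {
        m: int((labels.codes == m).sum()) for m in range(labels.M)
    }
    return {
        "n": labels.n,
        "n_labeled": labels.n_labeled,
        "n_unlabeled": labels.n_unlabeled,
        "labeled_per_class": per_class,
    }
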