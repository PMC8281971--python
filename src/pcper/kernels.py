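"""Kernel functions, multi-kernel combination, and data-driven defaults.

Five base kernels are supported:

    linear                   <x, z>
    rbf                      exp(-gamma * ||x - z||^2)
    laplacian                exp(-sigma * ||x - z||)
    inverse_square_distance  1 / (1 + sigma * ||x - z||^2)
    inverse_distance         1 / (1 + sigma * ||x - z||)

plus ``precomputed`` (a user-supplied Gram matrix) and ``multi``, the
orthogonal concatenation of several feature maps. Concatenating maps
phi_1, ..., phi_P gives <phi~(x), phi~(z)> = sum_p K_p(x, z), so the
combined Gram is the elementwise sum of the component Grams.

Widths may be the string "auto", in which case they are resolved from the
mean pairwise Euclidean distance sigma_bar of the data: gamma = 1/(2
sigma_bar^2) for rbf, sigma = 1/sigma_bar for the first-power distance
kernels (laplacian, inverse_distance) and sigma = 1/sigma_bar^2 for
inverse_square_distance, so that each exponent/denominator is O(1) at a
typical inter-point distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics.pairwise import linear_kernel, rbf_kernel

from .errors import ConfigurationError, InvalidInputError
from .graph import _as_matrix, mean_pairwise_distance

KERNEL_NAMES = (
    "linear",
    "rbf",
    "laplacian",
    "inverse_square_distance",
    "inverse_distance",
    "precomputed",
    "multi",
)


@dataclass
class KernelConfig:
    """Declarative kernel specification.

    Parameters
    ----------
    name : str
        One of ``KERNEL_NAMES``.
    width : float or "auto"
        gamma for rbf, sigma for the distance kernels; ignored by linear
        and precomputed.
    components : list of KernelConfig
        Only for ``multi``; at least one component.
    """

    name: str = "rbf"
    width: float | str = "auto"
    components: list["KernelConfig"] = field(default_factory=list)

    def __post_init__(self):
        if self.name not in KERNEL_NAMES:
            raise ConfigurationError(
                f"unknown kernel {self.name!r}; choose from {KERNEL_NAMES}"
            )
        if self.name == "multi" and not self.components:
            raise ConfigurationError("multi kernel needs at least one component")

    def resolve(self, X) -> "KernelConfig":
        """Return a copy with every "auto" width fixed from the data."""
        if self.name == "multi":
            return KernelConfig(
                "multi", self.width, [c.resolve(X) for c in self.components]
            )
        if self.name in ("linear", "precomputed") or not isinstance(self.width, str):
            return KernelConfig(self.name, self.width, [])
        if self.width != "auto":
            raise ConfigurationError(f"width must be positive or 'auto', got {self.width!r}")
        sb = mean_pairwise_distance(X)
        if sb == 0:
            raise InvalidInputError("all instances identical; cannot auto-resolve width")
        if self.name == "rbf":
            w = 1.0 / (2.0 * sb**2)
        elif self.name == "inverse_square_distance":
            w = 1.0 / sb**2
        else:  # laplacian, inverse_distance: first power of distance
            w = 1.0 / sb
        return KernelConfig(self.name, w, [])

    def to_dict(self) -> dict:
        d = {"name": self.name, "width": self.width}
        if self.components:
            d["components"] = [c.to_dict() for c in self.components]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "KernelConfig":
        return cls(
            d.get("name", "rbf"),
            d.get("width", "auto"),
            [cls.from_dict(c) for c in d.get("components", [])],
        )


def parse_kernel_spec(spec: str) -> KernelConfig:
    """Parse a compact kernel string.

    ``"rbf"``, ``"rbf:0.5"``, ``"laplacian:auto"``; a '+'-joined list
    builds a multi kernel: ``"rbf:auto+linear"``.
    """
    parts = [p.strip() for p in spec.split("+") if p.strip()]
    if not parts:
        raise ConfigurationError(f"empty kernel spec {spec!r}")

    def one(p: str) -> KernelConfig:
        name, _, width = p.partition(":")
        if not width:
            return KernelConfig(name)
        try:
            w = float(width)
        except ValueError:
            w = width
        return KernelConfig(name, w)

    if len(parts) == 1:
        return one(parts[0])
    return KernelConfig("multi", components=[one(p) for p in parts])


def _require_width(cfg: KernelConfig) -> float:
    if isinstance(cfg.width, str):
        raise ConfigurationError(
            f"kernel {cfg.name!r} width is unresolved ({cfg.width!r}); call resolve(X)"
        )
    w = float(cfg.width)
    if w <= 0:
        raise ConfigurationError(f"kernel width must be > 0, got {w}")
    return w


def gram(Xa, Xb, cfg: KernelConfig) -> np.ndarray:
    """Gram matrix between the rows of ``Xa`` and ``Xb`` under ``cfg``.

    "auto" widths are resolved on ``Xa`` (pass a pre-resolved config to pin
    the training-data widths at prediction time).
    """
    if cfg.name == "precomputed":
        raise ConfigurationError("precomputed kernels carry their own Gram matrix")
    Xa = _as_matrix(Xa, "Xa")
    Xb = _as_matrix(Xb, "Xb")
    if Xa.shape[1] != Xb.shape[1]:
        raise InvalidInputError(
            f"feature dimension mismatch: {Xa.shape[1]} vs {Xb.shape[1]}"
        )
    if cfg.name == "multi":
        return multi_kernel_combine([gram(Xa, Xb, c) for c in cfg.components])
    cfg = cfg.resolve(Xa)
    if cfg.name == "linear":
        return linear_kernel(Xa, Xb)
    w = _require_width(cfg)
    if cfg.name == "rbf":
        return rbf_kernel(Xa, Xb, gamma=w)
    D = cdist(Xa, Xb)
    if cfg.name == "laplacian":
        return np.exp(-w * D)
    if cfg.name == "inverse_square_distance":
        return 1.0 / (1.0 + w * D**2)
    if cfg.name == "inverse_distance":
        return 1.0 / (1.0 + w * D)
    raise ConfigurationError(f"unknown kernel {cfg.name!r}")  # pragma: no cover


def multi_kernel_combine(grams: list[np.ndarray]) -> np.ndarray:
    """Elementwise sum of component Gram matrices — the Gram of the
    orthogonally concatenated feature map."""
    if not grams:
        raise InvalidInputError("need at least one Gram matrix")
    out = np.asarray(grams[0], dtype=float).copy()
    for G in grams[1:]:
        G = np.asarray(G, dtype=float)
        if G.shape != out.shape:
            raise InvalidInputError(
                f"Gram shape mismatch: {G.shape} vs {out.shape}"
            )
        out += G
    return out


def validate_precomputed(K, tol: float = 1e-8) -> np.ndarray:
    """Check and return a user-supplied square Gram matrix (symmetric within
    ``tol``)."""
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise InvalidInputError(f"precomputed Gram must be square, got {K.shape}")
    if not np.all(np.isfinite(K)):
        raise InvalidInputError("precomputed Gram contains non-finite entries")
    if np.max(np.abs(K - K.T)) > tol * max(1.0, np.max(np.abs(K))):
        raise InvalidInputError("precomputed Gram is not symmetric within tolerance")
    return 0.5 * (K + K.T)


def c_heuristic(X) -> float:
    """Data-divergence default for the entropy weight C:
    mean Euclidean distance of the instances from their centroid,
    C = sum_j ||x_j - x_bar|| / n."""
    X = _as_matrix(X)
    xbar = X.mean(axis=0)
    return float(np.linalg.norm(X - xbar, axis=1).mean())
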