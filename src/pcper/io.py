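"""Delimited-text I/O and model (de)serialization.

Feature tables are plain delimited text (comma or tab), one row per
instance; labels are one integer per row with -1 marking unlabeled
instances. Writers emit shortest-roundtrip floats so a write -> read
cycle reproduces values exactly.

A fitted model is serialized as a JSON document holding the dual
coefficients, the training features, the resolved kernel/graph/hyper
configuration and the objective trace. The Gram matrices are rebuilt
deterministically on load, so save -> load -> predict is bit-stable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GramPair, Hyperparams, LabelSet, PCPModel
from .errors import InvalidInputError, ParseError
from .graph import build_knn_graph
from .kernels import KernelConfig, gram, validate_precomputed

FORMAT_VERSION = 1


def read_features(path, delimiter: str = ",", header: bool = False) -> np.ndarray:
    """Read a numeric feature table; raises :class:`ParseError` naming the
    offending row for ragged or non-numeric input."""
    try:
        df = pd.read_csv(path, sep=delimiter, header=0 if header else None,
                         comment="#", skip_blank_lines=True,
                         float_precision="round_trip")
    except pd.errors.ParserError as e:
        raise ParseError(f"{path}: {e}") from e
    except pd.errors.EmptyDataError as e:
        raise ParseError(f"{path}: empty file") from e
    raw = df.to_numpy()
    num = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(np.isnan(num) & ~pd.isna(raw))
    if bad.size:
        r, c = bad[0]
        raise ParseError(
            f"{path}: non-numeric value {raw[r, c]!r} at row {r + 1}, column {c + 1}"
        )
    if np.any(pd.isna(raw)):
        r = int(np.argwhere(pd.isna(raw))[0][0])
        raise ParseError(f"{path}: missing value / ragged row at row {r + 1}")
    return num


def read_gram(path, delimiter: str = ",", header: bool = False) -> np.ndarray:
    """Read a precomputed square Gram matrix from a delimited table."""
    K = read_features(path, delimiter, header)
    return validate_precomputed(K)


def read_labels(path, M: int | None = None) -> LabelSet:
    """Read one integer class code per row (-1 = unlabeled).

    If ``M`` is given, codes >= M are a parse error; otherwise M is
    inferred from the largest code present.
    """
    codes = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            try:
                v = int(s)
            except ValueError:
                raise ParseError(f"{path}: non-integer label {s!r} at row {i}") from None
            if v < -1 or (M is not None and v >= M):
                raise ParseError(
                    f"{path}: label {v} at row {i} outside {{-1, 0, ..., "
                    f"{(M - 1) if M is not None else '...'}}}"
                )
            codes.append(v)
    if not codes:
        raise ParseError(f"{path}: no labels found")
    return LabelSet.from_codes(np.asarray(codes), M)


def write_features(path, X, delimiter: str = ",") -> None:
    np.savetxt(path, np.atleast_2d(X), fmt="%.17g", delimiter=delimiter)


def write_labels(path, codes) -> None:
    np.savetxt(path, np.asarray(codes, dtype=int)[:, None], fmt="%d")


def write_predictions(path, codes) -> None:
    write_labels(path, codes)


def write_memberships(path, W, delimiter: str = ",") -> None:
    """Write an (n, M) membership (or decision-value) table."""
    write_features(path, W, delimiter)


# ---------------------------------------------------------------------------
# model serialization


def save_model(path, model: PCPModel) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "hard": model.hard,
        "alpha": model.alpha.tolist(),
        "kernel": model.kernel.to_dict(),
        "labels": {"codes": model.labels.codes.tolist(), "M": model.labels.M},
        "hyper": {
            "lambda": model.hyper.lambda_,
            "lambda_s": model.hyper.lambda_s,
            "C": model.hyper.C,
            "k": model.hyper.k,
            "gamma": model.hyper.gamma,
            "epsilon": model.hyper.epsilon,
            "max_iter": model.hyper.max_iter,
            "init": model.hyper.init,
        },
        "Xtrain": None if model.Xtrain is None else model.Xtrain.tolist(),
        "Ktrain": model.Ktrain.tolist() if model.Xtrain is None else None,
        "objective_trace": model.objective_trace,
        "converged": model.converged,
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path) -> PCPModel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ParseError(f"{path}: not a valid model file ({e})") from e
    if doc.get("format_version") != FORMAT_VERSION:
        raise ParseError(
            f"{path}: unsupported model format version {doc.get('format_version')!r}"
        )
    labels = LabelSet(np.asarray(doc["labels"]["codes"]), doc["labels"]["M"])
    h = doc["hyper"]
    hyper = Hyperparams(
        lambda_=h["lambda"], lambda_s=h["lambda_s"], C=h["C"], k=h["k"],
        gamma=h["gamma"], epsilon=h["epsilon"], max_iter=h["max_iter"],
        init=h.get("init", "zeros"),
    )
    kernel = KernelConfig.from_dict(doc["kernel"])
    alpha = np.asarray(doc["alpha"], dtype=float)
    if doc["Xtrain"] is not None:
        Xtrain = np.asarray(doc["Xtrain"], dtype=float)
        graph = build_knn_graph(Xtrain, hyper.k, hyper.gamma)
        K = gram(Xtrain, Xtrain, kernel)
    else:
        if doc.get("Ktrain") is None:
            raise ParseError(f"{path}: precomputed model is missing its Gram matrix")
        Xtrain = None
        K = np.asarray(doc["Ktrain"], dtype=float)
        from .core import _graph_from_gram

        graph = _graph_from_gram(K, hyper.k, hyper.gamma)
    gp = GramPair.from_graph(K, graph)
    if alpha.shape != (labels.M, labels.n):
        raise InvalidInputError(
            f"{path}: alpha shape {alpha.shape} inconsistent with labels"
        )
    return PCPModel(
        alpha=alpha, kernel=kernel, labels=labels, hyper=hyper, Xtrain=Xtrain,
        Ktrain=gp.K, K_bar=gp.K_bar, graph=graph,
        objective_trace=list(doc.get("objective_trace", [])),
        converged=bool(doc.get("converged", False)),
        hard=bool(doc.get("hard", False)),
    )
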