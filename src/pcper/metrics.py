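"""Evaluation metrics for predicted class codes."""

from __future__ import annotations

import numpy as np
from sklearn.metrics import confusion_matrix

from .errors import InvalidInputError


def evaluate(pred, truth, mask=None) -> dict:
    """Accuracy, per-class accuracy, and confusion counts.

    ``mask`` optionally restricts the evaluation to a subset (e.g. the
    unlabeled non-outlier instances). Rows whose truth code is negative
    (no ground-truth class, e.g. injected outliers) are excluded.
    """
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise InvalidInputError(
            f"prediction/truth length mismatch: {pred.shape} vs {truth.shape}"
        )
    keep = truth >= 0
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != truth.shape:
            raise InvalidInputError("mask length mismatch")
        keep &= mask
    pred, truth = pred[keep], truth[keep]
    if pred.size == 0:
        raise InvalidInputError("no instances left to evaluate")
    classes = np.arange(max(truth.max(), pred.max()) + 1)
    cm = confusion_matrix(truth, pred, labels=classes)
    per_class = {}
    for m in classes:
        total = cm[m].sum()
        per_class[int(m)] = float(cm[m, m] / total) if total else float("nan")
    return {
        "n": int(pred.size),
        "accuracy": float((pred == truth).mean()),
        "per_class_accuracy": per_class,
        "confusion": cm.tolist(),
    }
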