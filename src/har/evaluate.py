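"""Instantaneous-prediction scoring.

Accuracy is computed on per-sample labels so that every segmentation scheme
— adaptive or fixed — is scored on exactly the same denominator.  Samples
with unlabeled ground truth are excluded from the matrix and reported as a
separate count.

Both per-class ratio families are computed and explicitly named:
``row_ratio`` = diagonal / row total (fraction of a true class predicted
correctly) and ``col_ratio`` = diagonal / column total (fraction of a
predicted class that is correct).  Published HAR tables are not always
consistent about which of these they call recall/precision, so this module
refuses to pick sides.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import nan

import numpy as np
import pandas as pd

from .classify import PredictionTrace


@dataclass
class ConfusionMatrix:
    """Square count matrix; rows = true class, columns = predicted class."""

    matrix: np.ndarray
    classes: tuple[str, ...]
    n_unlabeled: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        k = len(self.classes)
        if self.matrix.shape != (k, k):
            raise ValueError(f"matrix shape {self.matrix.shape} does not match {k} classes")
        if (self.matrix < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.classes), columns=list(self.classes))


def confusion_matrix(
    truth: PredictionTrace, pred: PredictionTrace, classes: tuple[str, ...] | None = None
) -> ConfusionMatrix:
    """Count matrix of (true, predicted) label pairs over equal-length traces."""
    if len(truth) != len(pred):
        raise ValueError(f"trace lengths differ: {len(truth)} vs {len(pred)}")
    t = truth.labels
    p = pred.labels
    labeled = t != None  # noqa: E711
    n_unlabeled = int((~labeled).sum())
    t, p = t[labeled], p[labeled]
    if classes is None:
        classes = tuple(sorted(set(t) | set(p[p != None])))  # noqa: E711
    index = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    M = np.zeros((k, k), dtype=np.int64)
    for ti, pi in zip(t, p):
        if ti not in index:
            raise ValueError(f"true label {ti!r} not in class set {classes}")
        if pi not in index:
            raise ValueError(f"predicted label {pi!r} not in class set {classes}")
        M[index[ti], index[pi]] += 1
    return ConfusionMatrix(M, tuple(classes), n_unlabeled)


def summarize(cm: ConfusionMatrix) -> dict:
    """Overall accuracy plus both per-class diagonal ratios, in percent.

    Classes with a zero denominator are reported as NaN (undefined), never 0.
    """
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(cm.matrix).astype(float)
    row_tot = cm.matrix.sum(axis=1).astype(float)
    col_tot = cm.matrix.sum(axis=0).astype(float)
    row_ratio = {
        c: (100.0 * diag[i] / row_tot[i] if row_tot[i] > 0 else nan)
        for i, c in enumerate(cm.classes)
    }
    col_ratio = {
        c: (100.0 * diag[i] / col_tot[i] if col_tot[i] > 0 else nan)
        for i, c in enumerate(cm.classes)
    }
    return {
        "accuracy_pct": 100.0 * diag.sum() / total,
        "correct": int(diag.sum()),
        "total": total,
        "n_unlabeled": cm.n_unlabeled,
        "row_ratio_pct": row_ratio,
        "col_ratio_pct": col_ratio,
    }


def window_size_sweep(train, test, config) -> pd.DataFrame:
    """Accuracy of every fixed window size plus adaptive segmentation.

    ``train``/``test`` are lists of (SensorStream, LabelTrack) pairs (already
    preprocessed); ``config`` is an :class:`har.pipeline.ExperimentConfig`.
    All methods are scored instantaneously on the identical held-out
    samples.  Returns a DataFrame with columns method, size_s, accuracy_pct.
    """
    from . import pipeline  # local import to avoid a cycle

    rows = []
    for size_s in config.sizes_s:
        res = pipeline.run_experiment(train, test, method="fixed", size_s=size_s, config=config)
        rows.append(("fixed", size_s, res.accuracy_pct))
    res = pipeline.run_experiment(train, test, method="ggs", config=config)
    rows.append(("ggs", np.nan, res.accuracy_pct))
    return pd.DataFrame(rows, columns=["method", "size_s", "accuracy_pct"])
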