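"""Gradient-boosted-tree activity classification on segment features.

Segments are labeled from ground truth by majority vote (ties broken by the
label occurring earliest in the segment); an XGBoost multiclass model is
trained on the 168-feature rows; and segment predictions are broadcast to
every sample they cover ("instantaneous" predictions), the common currency
for comparing segmentation schemes.

The boosting library is called, not re-implemented.  Default
hyperparameters follow the published configuration: 200 trees, learning
rate 0.1, depth 2 or 3 depending on profile, multi:softprob objective.
Training rows are canonically sorted before fitting so the fitted model is
exactly invariant to input row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from xgboost import XGBClassifier

from .features import FEATURE_NAMES
from .sensor_io import LabelTrack


@dataclass
class ModelSpec:
    """Hyperparameters for the gradient-boosted-tree classifier."""

    n_trees: int = 200
    learning_rate: float = 0.1
    max_depth: int = 3
    subsample: float = 1.0
    colsample_bytree: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")


@dataclass
class FittedModel:
    """A fitted multiclass booster plus its label/feature schema."""

    clf: XGBClassifier
    classes: tuple[str, ...]
    feature_names: tuple[str, ...]


@dataclass
class PredictionTrace:
    """One activity label per sample over [0, T)."""

    labels: np.ndarray  # object dtype; None marks unlabeled
    provenance: str = "truth"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)

    def __len__(self) -> int:
        return len(self.labels)


def assign_segment_labels(
    segments: list[tuple[int, int]], truth: LabelTrack, T: int | None = None
) -> pd.DataFrame:
    """Majority ground-truth label and purity per segment.

    Ties go to the tied label occurring earliest in the segment.  Segments
    whose samples are entirely unlabeled get label None (callers drop them
    from training).  Purity is the majority fraction among labeled samples.
    """
    if T is None:
        T = max((e for _, e in segments), default=0)
    sample_labels = truth.to_sample_labels(T)
    rows = []
    for start, end in segments:
        seg = sample_labels[start:end]
        labeled = seg[seg != None]  # noqa: E711  (object-array comparison)
        if len(labeled) == 0:
            rows.append((start, end, None, 0.0))
            continue
        counts: dict[str, int] = {}
        first_pos: dict[str, int] = {}
        for k, lab in enumerate(seg):
            if lab is None:
                continue
            counts[lab] = counts.get(lab, 0) + 1
            first_pos.setdefault(lab, k)
        best = max(counts, key=lambda lab: (counts[lab], -first_pos[lab]))
        rows.append((start, end, best, counts[best] / len(labeled)))
    return pd.DataFrame(rows, columns=["start", "end", "label", "purity"])


def _feature_frame(F: pd.DataFrame) -> pd.DataFrame:
    """Extract the feature columns, validating the schema."""
    missing = [c for c in FEATURE_NAMES if c not in F.columns]
    if missing:
        raise ValueError(f"feature matrix is missing columns: {missing[:5]}...")
    return F[list(FEATURE_NAMES)]


def train_classifier(F: pd.DataFrame, y, spec: ModelSpec | None = None) -> FittedModel:
    """Fit the multiclass booster on segment features.

    Deterministic given ``spec.seed`` and invariant to the order of the
    training rows (rows are canonically sorted internally).
    """
    spec = spec or ModelSpec()
    X = _feature_frame(F).to_numpy(dtype=np.float64)
    y = np.asarray(list(y), dtype=object)
    if len(y) != len(X):
        raise ValueError(f"{len(X)} feature rows but {len(y)} labels")
    bad = ~np.isfinite(X)
    if bad.any():
        j = int(np.argwhere(bad)[0][1])
        raise ValueError(f"non-finite values in feature column {FEATURE_NAMES[j]!r}")
    classes = tuple(sorted(set(y)))
    if len(classes) < 2:
        raise ValueError(f"need at least 2 classes to train, got {classes}")
    codes = np.array([classes.index(lab) for lab in y])
    # canonical row order -> fit independent of caller's row order
    order = np.lexsort(tuple(X.T) + (codes,))
    # the soft-probability multiclass objective needs >= 3 classes in the
    # underlying library; binary problems use the logistic objective
    objective = "multi:softprob" if len(classes) > 2 else "binary:logistic"
    clf = XGBClassifier(
        n_estimators=spec.n_trees,
        learning_rate=spec.learning_rate,
        max_depth=spec.max_depth,
        subsample=spec.subsample,
        colsample_bytree=spec.colsample_bytree,
        objective=objective,
        tree_method="hist",
        n_jobs=1,
        random_state=spec.seed,
        reg_lambda=1.0,
    )
    clf.fit(X[order], codes[order])
    return FittedModel(clf, classes, tuple(FEATURE_NAMES))


def predict_segments(model: FittedModel, F: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-segment labels and class probabilities (rows sum to 1)."""
    feature_cols = [c for c in F.columns if c in model.feature_names]
    extra = set(feature_cols) - set(model.feature_names)
    missing = [c for c in model.feature_names if c not in F.columns]
    if missing or extra:
        raise ValueError(f"feature schema mismatch; missing={missing[:5]} extra={sorted(extra)[:5]}")
    X = F[list(model.feature_names)].to_numpy(dtype=np.float64)
    proba = model.clf.predict_proba(X)
    labels = np.asarray([model.classes[k] for k in proba.argmax(axis=1)], dtype=object)
    return labels, pd.DataFrame(proba, columns=list(model.classes))


def to_instantaneous(
    seg_preds, segments: list[tuple[int, int]], T: int, provenance: str = "ggs"
) -> PredictionTrace:
    """Broadcast each segment's label to all of its samples."""
    segs = sorted(segments)
    if not segs or segs[0][0] != 0 or segs[-1][1] != T:
        raise ValueError(f"segments do not cover [0, {T})")
    for (a0, a1), (b0, b1) in zip(segs, segs[1:]):
        if a1 != b0:
            raise ValueError(f"segments are not a partition: gap/overlap at {a1} vs {b0}")
    out = np.empty(T, dtype=object)
    for (start, end), lab in zip(segments, seg_preds):
        out[start:end] = lab
    return PredictionTrace(out, provenance)


def feature_importances(model: FittedModel, top_n: int = 15) -> pd.DataFrame:
    """Top features by gain importance, scores non-increasing."""
    booster = model.clf.get_booster()
    booster.feature_names = list(model.feature_names)
    raw = booster.get_score(importance_type="gain")
    scores = [(name, raw.get(name, 0.0)) for name in model.feature_names]
    scores.sort(key=lambda kv: -kv[1])
    return pd.DataFrame(scores[:top_n], columns=["feature", "score"])
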