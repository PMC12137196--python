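"""Random-forest behaviour classification with OOB tuning and MCC metrics.

A 1000-tree random forest maps the 36 window features to the four-behaviour
ethogram. The number of predictors tried at each split (mtry) is selected by
comparing out-of-bag (OOB) error over a candidate grid; the OOB error — the
misclassification rate of each training window by the trees that did not
sample it — also serves as the headline performance estimate, together with
a 4x4 observed-vs-predicted confusion matrix and per-class precision, recall
and Matthews correlation coefficient (one-vs-rest), the latter preferred
because the training set is heavily imbalanced (running is rare).

Everything is deterministic given the seed; vote ties are broken by the fixed
class order (feeding, resting, running, walking), which coincides with the
sorted label order used by the underlying ensemble.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .ethogram import CLASS_ORDER
from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

#: Candidate mtry grid: geometric neighbourhood of floor(sqrt(36)) = 6,
#: emulating a doubling/halving OOB search.
DEFAULT_MTRY_CANDIDATES: tuple[int, ...] = (3, 6, 9, 12, 18)


@dataclass(frozen=True)
class ForestConfig:
    """Hyper-parameters of the behaviour forest."""

    n_trees: int = 1000
    mtry: int = 6
    seed: int = 0
    class_order: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 1 <= self.mtry <= len(FEATURE_NAMES):
            raise ValueError(f"mtry must be in [1, {len(FEATURE_NAMES)}]")


@dataclass
class ConfusionMatrix:
    """4x4 counts; rows are observed behaviours, columns predictions."""

    counts: np.ndarray
    class_order: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}")
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> dict[str, int]:
        return dict(zip(self.class_order, self.counts.sum(axis=1).tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_order, columns=self.class_order)


@dataclass
class ClassMetrics:
    """Per-class one-vs-rest performance plus overall error/accuracy.

    Zero-denominator metrics are NaN (undefined), never silently 0.
    """

    per_class: pd.DataFrame  # index class; columns TP, FP, TN, FN, precision, recall, mcc
    overall_error: float
    overall_accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        self.overall_accuracy = 1.0 - self.overall_error


@dataclass
class ForestModel:
    """A fitted forest with its schema and OOB evaluation."""

    estimator: RandomForestClassifier
    config: ForestConfig
    feature_order: tuple[str, ...]
    oob_error: float
    oob_confusion: ConfusionMatrix


def _validate_training(train: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    missing = [c for c in FEATURE_NAMES if c not in train.columns]
    if missing:
        raise ValueError(f"training table is missing feature columns {missing}")
    X = train[list(FEATURE_NAMES)].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("training features must all be finite")
    y = train["label"].to_numpy(dtype=object)
    bad = sorted(set(y) - set(CLASS_ORDER))
    if bad:
        raise ValueError(f"labels outside the ethogram: {bad}")
    absent = [c for c in CLASS_ORDER if c not in set(y)]
    if absent:
        raise ValueError(f"behaviour classes with 0 observations: {absent}")
    return X, y


def train_forest(train: pd.DataFrame, config: ForestConfig | None = None) -> ForestModel:
    """Fit the behaviour forest and evaluate it out-of-bag.

    ``train`` must hold the 36 feature columns plus a ``label`` column with
    all four behaviours present. Returns the fitted model with its OOB error
    and OOB confusion matrix (each training window predicted by the trees
    that did not bootstrap it, argmax vote with class-order tie-breaking).
    """
    config = ForestConfig() if config is None else config
    X, y = _validate_training(train)
    rf = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.mtry,
        oob_score=True,
        random_state=config.seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    # rf.classes_ is sorted, equal to CLASS_ORDER; argmax breaks ties toward
    # the first (lowest) class, i.e. the fixed class order.
    proba = rf.oob_decision_function_
    seen = proba.sum(axis=1) > 0  # windows never left out-of-bag have all-zero rows
    if not seen.all():
        logger.warning("%d training windows were never out-of-bag; excluded", int((~seen).sum()))
    oob_pred = np.asarray(rf.classes_)[np.argmax(proba[seen], axis=1)]
    cm = confusion(pred=oob_pred, obs=y[seen])
    oob_error = float(np.mean(oob_pred != y[seen]))
    logger.info("forest trained: mtry=%d, OOB error %.4f", config.mtry, oob_error)
    return ForestModel(rf, config, tuple(FEATURE_NAMES), oob_error, cm)


def tune_mtry(
    train: pd.DataFrame,
    n_trees: int = 1000,
    candidates: tuple[int, ...] = DEFAULT_MTRY_CANDIDATES,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Select mtry by lowest OOB error over a candidate grid.

    Fits one forest per candidate and returns ``(best_mtry, log)`` where the
    log table lists every candidate's OOB error. Ties go to the smallest
    candidate (the scan is in ascending order with strict improvement).
    """
    n_feat = len(FEATURE_NAMES)
    bad = [c for c in candidates if not 1 <= c <= n_feat]
    if bad:
        raise ValueError(f"mtry candidates out of [1, {n_feat}]: {bad}")
    records = []
    for m in sorted(candidates):
        model = train_forest(train, ForestConfig(n_trees=n_trees, mtry=m, seed=seed))
        records.append({"mtry": m, "oob_error": model.oob_error})
    log = pd.DataFrame(records)
    best = int(log.loc[log["oob_error"].idxmin(), "mtry"])
    logger.info("mtry tuning:\n%s\nselected mtry=%d", log.to_string(index=False), best)
    return best, log


def predict_behaviors(model: ForestModel, features: pd.DataFrame) -> pd.Series:
    """Predict one behaviour label per window (majority vote over trees)."""
    missing = [c for c in model.feature_order if c not in features.columns]
    if missing:
        raise ValueError(f"feature table is missing columns {missing}")
    if features.empty:
        return pd.Series([], dtype=object, name="label")
    X = features[list(model.feature_order)].to_numpy(dtype=float)
    proba = model.estimator.predict_proba(X)
    labels = np.asarray(model.estimator.classes_)[np.argmax(proba, axis=1)]
    return pd.Series(labels, index=features.index, name="label")


def confusion(pred, obs, class_order: tuple[str, ...] = CLASS_ORDER) -> ConfusionMatrix:
    """Observed-vs-predicted count matrix; counts[i, j] = #(obs=i, pred=j)."""
    pred = np.asarray(pred, dtype=object)
    obs = np.asarray(obs, dtype=object)
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must have equal length")
    index = {c: i for i, c in enumerate(class_order)}
    bad = sorted((set(pred) | set(obs)) - set(class_order))
    if bad:
        raise ValueError(f"labels outside the ethogram: {bad}")
    k = len(class_order)
    counts = np.zeros((k, k), dtype=np.int64)
    for o, p in zip(obs, pred):
        counts[index[o], index[p]] += 1
    return ConfusionMatrix(counts, class_order)


def metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Precision, recall and MCC per class (one-vs-rest), plus overall error.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); any metric
    with a zero denominator is reported as NaN. The overall error is the
    off-diagonal fraction of the matrix.
    """
    total = cm.total
    if total == 0:
        raise ValueError("confusion matrix has no observations")
    rows = []
    for i, cls in enumerate(cm.class_order):
        tp = int(cm.counts[i, i])
        fn = int(cm.counts[i].sum() - tp)
        fp = int(cm.counts[:, i].sum() - tp)
        tn = total - tp - fn - fp
        precision = tp / (tp + fp) if tp + fp > 0 else math.nan
        recall = tp / (tp + fn) if tp + fn > 0 else math.nan
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else math.nan
        rows.append(
            {
                "class": cls,
                "TP": tp,
                "FP": fp,
                "TN": tn,
                "FN": fn,
                "precision": precision,
                "recall": recall,
                "mcc": mcc,
            }
        )
    per_class = pd.DataFrame(rows).set_index("class")
    overall_error = float((total - np.trace(cm.counts)) / total)
    return ClassMetrics(per_class=per_class, overall_error=overall_error)


def save_model(model: ForestModel, path: str | Path) -> None:
    """Serialize the model with its schema to one file, plus a text sidecar
    reporting the OOB confusion matrix in observed-rows/predicted-columns
    layout."""
    path = Path(path)
    joblib.dump(
        {
            "estimator": model.estimator,
            "config": model.config,
            "feature_order": model.feature_order,
            "oob_error": model.oob_error,
            "oob_confusion_counts": model.oob_confusion.counts,
            "class_order": model.oob_confusion.class_order,
        },
        path,
    )
    sidecar = path.with_suffix(path.suffix + ".confusion.txt")
    m = metrics(model.oob_confusion)
    with open(sidecar, "w") as fh:
        fh.write("OOB confusion matrix (rows observed, columns predicted)\n")
        fh.write(model.oob_confusion.to_frame().to_string())
        fh.write(f"\n\nOOB error rate: {model.oob_error:.4f}\n\n")
        fh.write(m.per_class[["precision", "recall", "mcc"]].round(3).to_string())
        fh.write("\n")


def load_model(path: str | Path) -> ForestModel:
    blob = joblib.load(path)
    return ForestModel(
        estimator=blob["estimator"],
        config=blob["config"],
        feature_order=tuple(blob["feature_order"]),
        oob_error=float(blob["oob_error"]),
        oob_confusion=ConfusionMatrix(blob["oob_confusion_counts"], tuple(blob["class_order"])),
    )
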