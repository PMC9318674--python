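"""Random-forest depressed-mood classifier, protocol and metrics.

The protocol is a single random 3:1 participant split (test size rounded up),
a random forest of 1000 trees with maximum depth 100, and per-class
precision / recall / F1 plus accuracy on the held-out quarter.  Predictions
can be scored against either questionnaire cut-point labels or the clinician
diagnosis; aggregate rows are reported both macro- and support-weighted, with
the aggregation mode labeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features import FEATURE_GROUPS
from .types import Diagnosis


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SplitResult:
    train_ids: tuple
    test_ids: tuple
    seed: int


@dataclass
class ModelConfig:
    n_trees: int = 1000
    max_tree_depth: int = 100
    seed: int = 0
    label_source: str = "PHQ9"  # or "CESDR"

    def __post_init__(self) -> None:
        if self.n_trees <= 0 or self.max_tree_depth <= 0:
            raise ConfigurationError("hyperparameters must be positive")


def split_cohort(ids: Sequence, test_fraction: float = 0.25, seed: int = 0) -> SplitResult:
    """Uniformly random train/test partition with |test| = ceil(n * fraction)."""
    ids = list(ids)
    n = len(ids)
    if n < 4:
        raise ValueError(f"need at least 4 participants to split, got {n}")
    n_test = math.ceil(n * test_fraction)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test = tuple(ids[i] for i in sorted(perm[:n_test]))
    train = tuple(ids[i] for i in sorted(perm[n_test:]))
    return SplitResult(train_ids=train, test_ids=test, seed=seed)


def train_model(
    features: np.ndarray, labels: Sequence[int], config: Optional[ModelConfig] = None
) -> RandomForestClassifier:
    """Fit the depth-bounded random-forest ensemble on binary mood labels."""
    config = config or ModelConfig()
    y = np.asarray(labels, dtype=int)
    X = np.asarray(features, dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values; apply drop/impute first")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    model = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_tree_depth,
        random_state=config.seed,
        n_jobs=1,
    )
    model.fit(X, y)
    return model


def impute_train_means(
    train: pd.DataFrame, test: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing feature groups with training-set column means (no test leakage)."""
    means = train.mean(skipna=True)
    return train.fillna(means), test.fillna(means)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def f1_from_precision_recall(precision_pct: float, recall_pct: float) -> Optional[float]:
    """Harmonic mean of precision and recall, all on the percent scale."""
    if precision_pct is None or recall_pct is None:
        return None
    if precision_pct + recall_pct == 0:
        return 0.0
    return 2 * precision_pct * recall_pct / (precision_pct + recall_pct)


@dataclass
class ClassMetrics:
    precision: Optional[float]  # percent; None when undefined (no predicted positives)
    recall: Optional[float]
    f1: Optional[float]
    support: int


@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int
    tn: int
    per_class: dict[str, ClassMetrics] = field(default_factory=dict)
    accuracy: float = 0.0  # percent
    macro: dict[str, Optional[float]] = field(default_factory=dict)
    weighted: dict[str, Optional[float]] = field(default_factory=dict)
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        return {
            "confusion": {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn},
            "accuracy": self.accuracy,
            "per_class": {
                name: vars(m).copy() for name, m in self.per_class.items()
            },
            "macro": dict(self.macro),
            "weighted": dict(self.weighted),
            "n_excluded": self.n_excluded,
        }


def _class_metrics(tp: int, fp: int, fn: int) -> ClassMetrics:
    precision = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else None
    recall = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else None
    f1 = f1_from_precision_recall(precision, recall) if None not in (precision, recall) else None
    return ClassMetrics(precision, recall, f1, support=tp + fn)


def _aggregate(rows: list[ClassMetrics], weights: list[float]) -> dict[str, Optional[float]]:
    out: dict[str, Optional[float]] = {}
    for metric in ("precision", "recall", "f1"):
        vals = [getattr(r, metric) for r in rows]
        if any(v is None for v in vals):
            out[metric] = None
        else:
            out[metric] = float(np.average(vals, weights=weights))
    return out


def evaluate(predictions: Sequence[int], truth: Sequence[int]) -> EvalReport:
    """Per-class precision/recall/F1 (percent), accuracy, and both aggregates.

    Class 1 is "depressed" (positive).  A class with zero predicted positives
    has undefined precision, reported as missing rather than zero.
    """
    pred = np.asarray(predictions, dtype=int)
    true = np.asarray(truth, dtype=int)
    if pred.shape != true.shape:
        raise ValueError("predictions and truth must have equal length")
    tp = int(np.sum((pred == 1) & (true == 1)))
    fp = int(np.sum((pred == 1) & (true == 0)))
    fn = int(np.sum((pred == 0) & (true == 1)))
    tn = int(np.sum((pred == 0) & (true == 0)))
    positive = _class_metrics(tp, fp, fn)
    negative = _class_metrics(tn, fn, fp)  # negative class: swap roles
    report = EvalReport(tp=tp, fp=fp, fn=fn, tn=tn)
    report.per_class = {"depressed": positive, "non_depressed": negative}
    report.accuracy = 100.0 * (tp + tn) / max(len(true), 1)
    rows = [positive, negative]
    report.macro = _aggregate(rows, weights=[1.0, 1.0])
    supports = [max(positive.support, 0), max(negative.support, 0)]
    if sum(supports) > 0:
        report.weighted = _aggregate(rows, weights=supports)
    return report


def ablation_by_group(
    features: pd.DataFrame,
    labels: Sequence[int],
    split: SplitResult,
    config: Optional[ModelConfig] = None,
    groups: Optional[dict[str, slice]] = None,
) -> dict[str, float]:
    """Held-out accuracy (percent) per feature group plus the all-features model.

    Groups default to the three design blocks of the 33-feature matrix
    (sleep, activity = mobility + daily activity, expression).
    """
    config = config or ModelConfig()
    groups = dict(groups) if groups is not None else dict(FEATURE_GROUPS)
    y = pd.Series(np.asarray(labels, int), index=features.index)
    X_train = features.loc[list(split.train_ids)]
    X_test = features.loc[list(split.test_ids)]
    y_train, y_test = y.loc[X_train.index], y.loc[X_test.index]
    accuracies: dict[str, float] = {}
    for name, block in {**groups, "all": slice(None)}.items():
        cols = features.columns[block]
        if len(cols) == 0:
            raise ConfigurationError(f"feature group {name!r} selects no columns")
        model = train_model(X_train[cols].to_numpy(), y_train, config)
        pred = model.predict(X_test[cols].to_numpy())
        accuracies[name] = float(100.0 * np.mean(pred == y_test.to_numpy()))
    return accuracies


def compare_to_diagnosis(
    predictions: Sequence[int], diagnoses: Sequence[Optional[Diagnosis]]
) -> tuple[EvalReport, ClassMetrics]:
    """Score predictions against the clinician diagnosis.

    Returns the full report plus the depressed-class row (performance on the
    participants actually diagnosed with a depressive disorder).  Participants
    without a diagnosis are excluded and counted.
    """
    pred, truth = [], []
    n_excluded = 0
    for p, d in zip(predictions, diagnoses, strict=True):
        if d is None:
            n_excluded += 1
            continue
        pred.append(int(p))
        truth.append(1 if d == Diagnosis.DEPRESSIVE else 0)
    report = evaluate(pred, truth)
    report.n_excluded = n_excluded
    return report, report.per_class["depressed"]
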