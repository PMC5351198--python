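"""Holdout split, class balancing, Monte Carlo cross-validation and metrics.

The evaluation protocol: classes are forced to equal sizes by downsampling
the majority class; a stratified 10% holdout is set aside once; then, for
each of `n_folds` Monte Carlo folds, the remaining 90% is split into 80%
training / 20% testing (stratified), a random forest is trained on the
training part and confusion counts are recorded on both the fold's test
partition and the constant holdout.  Reported metrics are per-fold means.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .features import FeatureMatrix

METRIC_NAMES = ("se", "sp", "precision", "f_measure", "acc", "mcc")


class ConfusionCounts(NamedTuple):
    tp: int
    fp: int
    tn: int
    fn: int


class Metrics(NamedTuple):
    se: float
    sp: float
    precision: float
    f_measure: float
    acc: float
    mcc: float


def _ratio(num: float, den: float) -> float:
    return num / den if den else 0.0


def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> Metrics:
    """SE, SP, precision, F-measure, ACC and MCC from confusion counts.

    Any metric whose denominator is zero is defined as 0 so fold aggregation
    stays total.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fp + tn + fn < 1:
        raise ValueError("at least one prediction required")
    se = _ratio(tp, tp + fn)
    sp = _ratio(tn, tn + fp)
    precision = _ratio(tp, tp + fp)
    f_measure = _ratio(2 * precision * se, precision + se)
    acc = (tp + tn) / (tp + fp + tn + fn)
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fn) * (tn + fp))
    mcc = _ratio(tp * tn - fp * fn, denom)
    return Metrics(se, sp, precision, f_measure, acc, mcc)


def confusion_counts(y_true, y_pred, positive_label) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t = y_true == positive_label
    pos_p = y_pred == positive_label
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


@dataclass(frozen=True)
class SplitPlan:
    """Holdout / Monte Carlo cross-validation configuration."""

    holdout_fraction: float = 0.10
    train_fraction: float = 0.80
    n_folds: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.holdout_fraction < 1.0):
            raise ValueError("holdout_fraction must be in (0, 1)")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_folds < 1:
            raise ValueError("n_folds must be >= 1")

    @property
    def test_fraction(self) -> float:
        return 1.0 - self.train_fraction


@dataclass(frozen=True)
class FoldResult:
    fold: int
    test_counts: ConfusionCounts
    holdout_counts: ConfusionCounts
    test_metrics: Metrics
    holdout_metrics: Metrics


@dataclass
class PerformanceReport:
    """Per-fold confusion counts and metrics for test and holdout partitions."""

    folds: list[FoldResult]
    positive_label: str = ""

    def accuracy_distribution(self, partition: str = "test") -> np.ndarray:
        return np.array([self._metrics(f, partition).acc for f in self.folds])

    def mean_metrics(self, partition: str = "test") -> Metrics:
        values = np.array([self._metrics(f, partition) for f in self.folds])
        return Metrics(*values.mean(axis=0))

    @staticmethod
    def _metrics(fold: FoldResult, partition: str) -> Metrics:
        if partition == "test":
            return fold.test_metrics
        if partition == "holdout":
            return fold.holdout_metrics
        raise ValueError(f"unknown partition {partition!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.folds:
            for partition, counts, metrics in (
                ("test", f.test_counts, f.test_metrics),
                ("holdout", f.holdout_counts, f.holdout_metrics),
            ):
                rows.append(
                    {
                        "fold": f.fold,
                        "partition": partition,
                        "tp": counts.tp,
                        "fp": counts.fp,
                        "tn": counts.tn,
                        "fn": counts.fn,
                        **{m: getattr(metrics, m) for m in METRIC_NAMES},
                    }
                )
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for partition in ("test", "holdout"):
            means = self.mean_metrics(partition)
            rows.append({"partition": partition, **means._asdict()})
        return pd.DataFrame(rows)

    def write(self, path: str | os.PathLike) -> None:
        """One row per fold per partition, followed by a summary block."""
        with open(path, "w") as fh:
            fh.write(self.to_frame().to_csv(sep="\t", index=False, float_format="%.6f"))
            fh.write("\n# summary (means over folds)\n")
            fh.write(
                self.summary_frame().to_csv(sep="\t", index=False, float_format="%.6f")
            )


def child_seed(seed: int, *key: int) -> int:
    """Derive a reproducible sub-seed (< 2**31) from a master seed and key."""
    ss = np.random.SeedSequence(seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def balance_classes(matrix: FeatureMatrix, seed: int = 0) -> FeatureMatrix:
    """Downsample the majority class uniformly without replacement.

    Row order of the retained examples is preserved; deterministic given
    `seed`.
    """
    counts = matrix.y.value_counts()
    if len(counts) < 2 or counts.min() == 0:
        raise ValueError("both classes need at least one example")
    minority = int(counts.min())
    rng = np.random.default_rng(seed)
    keep = np.zeros(matrix.n_examples, dtype=bool)
    y = matrix.y.to_numpy()
    for label in counts.index:
        positions = np.flatnonzero(y == label)
        if positions.size > minority:
            positions = rng.choice(positions, size=minority, replace=False)
        keep[positions] = True
    return matrix.subset_rows(matrix.X.index[keep])


def default_classifier_factory(n_trees: int = 100) -> Callable[[int], RandomForestClassifier]:
    """Random forest with sqrt(n_features) candidate splits and no depth cap."""

    def factory(random_state: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            n_jobs=1,
            random_state=random_state,
        )

    return factory


def _positive_label(y: pd.Series, positive_label: str | None) -> str:
    if positive_label is not None:
        if positive_label not in set(y):
            raise ValueError(f"positive label {positive_label!r} not present")
        return positive_label
    labels = list(dict.fromkeys(y))  # order of first appearance
    if "positive" in labels:
        return "positive"
    return labels[0]


def _stratified_split(indices, y, test_fraction, random_state, max_retries=10):
    """Stratified split that redraws if a partition ends up single-class."""
    for attempt in range(max_retries):
        a, b = train_test_split(
            indices,
            test_size=test_fraction,
            stratify=y.loc[indices],
            random_state=(random_state + attempt) % (2**31),
        )
        if y.loc[a].nunique() == 2 and y.loc[b].nunique() == 2:
            return a, b
    raise RuntimeError("could not draw a split with both classes in each partition")


def mccv_run(
    matrix: FeatureMatrix,
    plan: SplitPlan,
    n_trees: int = 100,
    classifier_factory: Callable[[int], object] | None = None,
    positive_label: str | None = None,
) -> PerformanceReport:
    """Monte Carlo cross-validation with a constant stratified holdout.

    One stratified `holdout_fraction` split is made up front; every fold draws
    a fresh stratified train/test split of the remainder, trains a classifier
    (random forest by default) and records confusion counts on the fold's
    test partition and on the holdout.  Fully deterministic given `plan.seed`.
    """
    if matrix.y.nunique() != 2:
        raise ValueError("exactly two classes required")
    pos = _positive_label(matrix.y, positive_label)
    if classifier_factory is None:
        classifier_factory = default_classifier_factory(n_trees)
    indices = matrix.X.index
    rest_idx, hold_idx = _stratified_split(
        indices, matrix.y, plan.holdout_fraction, child_seed(plan.seed, 0)
    )
    X_hold, y_hold = matrix.X.loc[hold_idx], matrix.y.loc[hold_idx]
    folds: list[FoldResult] = []
    for fold in range(plan.n_folds):
        train_idx, test_idx = _stratified_split(
            rest_idx, matrix.y, plan.test_fraction, child_seed(plan.seed, 1, fold)
        )
        clf = classifier_factory(child_seed(plan.seed, 2, fold))
        clf.fit(matrix.X.loc[train_idx], matrix.y.loc[train_idx])
        test_counts = confusion_counts(
            matrix.y.loc[test_idx], clf.predict(matrix.X.loc[test_idx]), pos
        )
        hold_counts = confusion_counts(y_hold, clf.predict(X_hold), pos)
        folds.append(
            FoldResult(
                fold=fold,
                test_counts=test_counts,
                holdout_counts=hold_counts,
                test_metrics=compute_metrics(*test_counts),
                holdout_metrics=compute_metrics(*hold_counts),
            )
        )
    return PerformanceReport(folds=folds, positive_label=pos)
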