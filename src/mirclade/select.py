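"""Information-gain feature ranking and top-N selection.

Information gain is the reduction in class entropy achieved by conditioning
on a discretized feature (equivalently, the mutual information between the
binned feature and the class label), in bits.  Continuous features are
discretized by equal-frequency binning before the gain is computed; the top
N features (default 100) are retained, ties broken by feature name so the
ranking is reproducible.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureMatrix


@dataclass
class FeatureRanking:
    """All features ordered by information gain (descending, name-tiebreak)."""

    entries: list[tuple[str, float]]
    n_selected: int

    def __post_init__(self) -> None:
        if self.n_selected > len(self.entries):
            raise ValueError("n_selected exceeds number of ranked features")

    @property
    def selected_names(self) -> list[str]:
        return [name for name, _ in self.entries[: self.n_selected]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "rank": i + 1,
                "feature": name,
                "gain_bits": gain,
                "selected": int(i < self.n_selected),
            }
            for i, (name, gain) in enumerate(self.entries)
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def discretize(values, n_bins: int = 10) -> np.ndarray:
    """Equal-frequency binning: boundaries at empirical quantiles.

    Identical values always share a bin; the number of distinct bins is at
    most `n_bins` (a constant vector collapses to a single bin).
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return np.empty(0, dtype=np.int64)
    quantiles = np.quantile(values, np.arange(1, n_bins) / n_bins)
    boundaries = np.unique(quantiles)
    return np.searchsorted(boundaries, values, side="left").astype(np.int64)


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def information_gain(bin_labels, class_labels) -> float:
    """G = H(class) - sum_t P(t) H(class | t), in bits (base-2 logarithm)."""
    bins = np.asarray(bin_labels)
    classes = np.asarray(class_labels)
    if bins.shape[0] != classes.shape[0]:
        raise ValueError("bin and class label vectors must have equal length")
    if np.unique(classes).size < 2:
        warnings.warn("only one class present; information gain is 0", stacklevel=2)
        return 0.0
    table = pd.crosstab(pd.Series(bins), pd.Series(classes)).to_numpy()
    n = table.sum()
    h_class = _entropy(table.sum(axis=0))
    h_cond = sum(
        (row.sum() / n) * _entropy(row) for row in table if row.sum() > 0
    )
    return max(float(h_class - h_cond), 0.0)


def select_top(
    matrix: FeatureMatrix, n: int = 100, n_bins: int = 10
) -> tuple[FeatureRanking, FeatureMatrix]:
    """Rank every feature by information gain and keep the top `n` columns.

    Gains are computed on all examples in `matrix`; the reduced matrix keeps
    the selected columns in ranking order.
    """
    if n > matrix.n_features:
        raise ValueError(
            f"cannot select {n} features from a matrix with {matrix.n_features}"
        )
    if len(matrix.labels) < 2:
        raise ValueError("both classes must be present for feature selection")
    classes = matrix.y.to_numpy()
    gains = {
        name: information_gain(discretize(matrix.X[name].to_numpy(), n_bins), classes)
        for name in matrix.X.columns
    }
    entries = sorted(gains.items(), key=lambda kv: (-kv[1], kv[0]))
    ranking = FeatureRanking(entries=entries, n_selected=n)
    reduced = FeatureMatrix(X=matrix.X[ranking.selected_names], y=matrix.y)
    return ranking, reduced
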