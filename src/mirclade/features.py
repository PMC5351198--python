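"""Feature matrix container and assembly of k-mer + motif feature blocks."""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import LabelledDataset
from .kmers import KmerFeatureSet, enumerate_kmers, kmer_frequency_matrix
from .motifs import MotifProfile, score_motif_bank


@dataclass
class FeatureMatrix:
    """Examples x named features with a class label per example.

    `X` is indexed by example id; `y` is the aligned label series.
    """

    X: pd.DataFrame
    y: pd.Series

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.y.index):
            self.y = self.y.reindex(self.X.index)
        if self.y.isna().any():
            raise ValueError("every example needs a class label")
        if self.X.isna().any().any():
            raise ValueError("feature matrix must not contain missing values")
        if self.X.columns.duplicated().any():
            dupes = sorted(set(self.X.columns[self.X.columns.duplicated()]))
            raise ValueError(f"duplicate feature names: {dupes}")
        if self.X.index.duplicated().any():
            raise ValueError("duplicate example ids")

    @property
    def n_examples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def labels(self) -> list[str]:
        return sorted(self.y.unique())

    def subset_rows(self, index) -> "FeatureMatrix":
        return FeatureMatrix(X=self.X.loc[index], y=self.y.loc[index])

    def to_csv(self, path: str | os.PathLike) -> None:
        """Delimited text: first column example id, last column class."""
        frame = self.X.copy()
        frame["class"] = self.y
        frame.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "FeatureMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        if "class" not in frame.columns:
            raise ValueError(f"{path}: missing 'class' column")
        y = frame.pop("class").astype(str)
        return cls(X=frame, y=y)


def build_feature_matrix(
    datasets: Sequence[LabelledDataset],
    profiles: Sequence[MotifProfile] = (),
    kmax: int = 3,
) -> FeatureMatrix:
    """Assemble the combined k-mer + motif-score feature matrix.

    With the defaults (kmax=3, 100 motifs per class for two classes) each
    example is described by 84 k-mer and 200 motif-score features.
    """
    if not datasets:
        raise ValueError("at least one labelled dataset required")
    feature_set: KmerFeatureSet = enumerate_kmers(kmax)
    blocks = []
    labels = []
    for ds in datasets:
        kmer_block = kmer_frequency_matrix(ds, feature_set)
        if profiles:
            motif_block = score_motif_bank(profiles, ds)
            block = pd.concat([kmer_block, motif_block], axis=1)
        else:
            block = kmer_block
        blocks.append(block)
        labels.extend([ds.label] * len(ds))
    X = pd.concat(blocks, axis=0)
    if X.index.duplicated().any():
        dupes = sorted(set(X.index[X.index.duplicated()]))
        raise ValueError(f"example id collision across datasets: {dupes}")
    y = pd.Series(labels, index=X.index, name="class")
    return FeatureMatrix(X=X, y=y)
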