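"""Fixed k-mer feature set and normalised k-mer frequencies.

Features are all words over {A,C,G,U} for k = 1..kmax (default 3, giving
4 + 16 + 64 = 84 features).  The frequency of a k-mer is its window count
divided by the number of valid windows of length k; windows containing an
ambiguous symbol are excluded from both numerator and denominator, so the
frequencies of each k still sum to one whenever at least one valid window
exists.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import ALPHABET, _ALPHABET_SET, LabelledDataset, SequenceRecord


@dataclass(frozen=True)
class KmerFeatureSet:
    """All k-mers for k = 1..kmax, ordered by k then lexicographically."""

    kmax: int
    names: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.names)


def enumerate_kmers(kmax: int) -> KmerFeatureSet:
    """Enumerate the complete k-mer feature set for k = 1..kmax."""
    if kmax < 1:
        raise ValueError(f"kmax must be >= 1, got {kmax}")
    names: list[str] = []
    for k in range(1, kmax + 1):
        names.extend("".join(t) for t in itertools.product(ALPHABET, repeat=k))
    return KmerFeatureSet(kmax=kmax, names=tuple(names))


def _residues(record: SequenceRecord | str) -> str:
    return getattr(record, "residues", record)


def kmer_frequencies(
    record: SequenceRecord | str, feature_set: KmerFeatureSet
) -> np.ndarray:
    """Normalised k-mer frequency vector aligned with `feature_set.names`.

    For each k the denominator is the number of windows of length k that are
    free of ambiguous symbols (len - k + 1 for a clean sequence); if none
    exists all k-mers of that k are 0.
    """
    seq = _residues(record)
    if len(seq) < 1:
        raise ValueError("sequence must have length >= 1")
    index = {name: i for i, name in enumerate(feature_set.names)}
    values = np.zeros(len(feature_set.names))
    for k in range(1, feature_set.kmax + 1):
        counts: Counter[str] = Counter()
        valid = 0
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if all(c in _ALPHABET_SET for c in window):
                counts[window] += 1
                valid += 1
        if valid == 0:
            continue
        for word, n in counts.items():
            values[index[word]] = n / valid
    return values


def kmer_frequency_matrix(
    records: Iterable[SequenceRecord] | LabelledDataset | Sequence[str],
    feature_set: KmerFeatureSet | None = None,
) -> pd.DataFrame:
    """k-mer frequencies for a collection of records (rows = record ids)."""
    if feature_set is None:
        feature_set = enumerate_kmers(3)
    if isinstance(records, LabelledDataset):
        records = records.records
    records = list(records)
    ids = [getattr(r, "id", f"seq{i}") for i, r in enumerate(records)]
    rows = np.vstack([kmer_frequencies(r, feature_set) for r in records])
    return pd.DataFrame(rows, index=pd.Index(ids, name="example_id"), columns=list(feature_set.names))
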