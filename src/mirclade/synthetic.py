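"""Synthetic paired sequence classes with a controlled divergence knob.

The generator emulates hairpin-scale sequence sets (hundreds of sequences of
60-120 nt): per class, residues are drawn i.i.d. from a background
composition and, with a stated probability, a planted motif instance
(consensus with per-position mutations) overwrites a uniformly chosen
window.  A divergence knob d in [0, 1] interpolates class B towards its own
target distribution: B's background = (1-d) * A's background + d * B's
target, and B's motif set replaces A's with probability d per sequence.  At
d = 0 both classes are statistically identical; at d = 1 they are fully
divergent.  Sequences are linear, unstructured strings — no hairpin folding.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ALPHABET, LabelledDataset, SequenceRecord, write_fasta
from .kmers import enumerate_kmers, kmer_frequencies

_UNIFORM = (0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class PlantedMotif:
    """A consensus word planted with some probability and point mutations."""

    consensus: str
    occurrence_prob: float = 1.0
    mutation_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.consensus or any(c not in ALPHABET for c in self.consensus):
            raise ValueError("consensus must be a non-empty A/C/G/U string")
        if not (0.0 <= self.occurrence_prob <= 1.0):
            raise ValueError("occurrence probability must be in [0, 1]")
        if not (0.0 <= self.mutation_rate <= 0.5):
            raise ValueError("mutation rate must be in [0, 0.5]")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters for one paired two-class experiment."""

    n_per_class: int = 300
    length_range: tuple[int, int] = (60, 120)
    background_a: tuple[float, float, float, float] = _UNIFORM
    background_b: tuple[float, float, float, float] = _UNIFORM
    motifs_a: tuple[PlantedMotif, ...] = ()
    motifs_b: tuple[PlantedMotif, ...] = ()
    divergence: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, bg in (("background_a", self.background_a), ("background_b", self.background_b)):
            if len(bg) != 4 or abs(sum(bg) - 1.0) > 1e-6 or min(bg) < 0:
                raise ValueError(f"{name} must be 4 non-negative probabilities summing to 1")
        if not (0.0 <= self.divergence <= 1.0):
            raise ValueError("divergence must be in [0, 1]")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError("length_range must satisfy 1 <= min <= max")
        longest = max((len(m.consensus) for m in self.motifs_a + self.motifs_b), default=0)
        if longest > lo:
            raise ValueError(
                f"planted motif of length {longest} exceeds minimum sequence length {lo}"
            )


def _mutate(consensus: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0.0:
        return consensus
    out = []
    for c in consensus:
        if rng.random() < rate:
            choices = [a for a in ALPHABET if a != c]
            out.append(choices[rng.integers(0, 3)])
        else:
            out.append(c)
    return "".join(out)


def _generate_class(
    label: str,
    prefix: str,
    n: int,
    length_range: tuple[int, int],
    background: np.ndarray,
    motif_sets: Sequence[tuple[float, Sequence[PlantedMotif]]],
    rng: np.random.Generator,
) -> tuple[LabelledDataset, list[dict]]:
    """motif_sets: list of (probability of choosing this set, motifs)."""
    lo, hi = length_range
    records: list[SequenceRecord] = []
    provenance: list[dict] = []
    set_probs = np.array([p for p, _ in motif_sets])
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(list(ALPHABET), size=length, p=background))
        chosen = motif_sets[int(rng.choice(len(motif_sets), p=set_probs))][1]
        planted, position = False, -1
        for motif in chosen:
            if rng.random() < motif.occurrence_prob:
                w = len(motif.consensus)
                pos = int(rng.integers(0, length - w + 1))
                instance = _mutate(motif.consensus, motif.mutation_rate, rng)
                seq[pos : pos + w] = list(instance)
                planted, position = True, pos
        rec = SequenceRecord(id=f"{prefix}{i + 1:04d}", residues="".join(seq), species=label)
        records.append(rec)
        provenance.append(
            {"id": rec.id, "class": label, "motif_planted": int(planted), "position": position}
        )
    return LabelledDataset(records=tuple(records), label=label, provenance=("synthetic",)), provenance


def generate_dataset_with_provenance(
    spec: SyntheticSpec,
) -> tuple[LabelledDataset, LabelledDataset, pd.DataFrame]:
    """Generate both classes plus a provenance table of planted positions."""
    rng = np.random.default_rng(spec.seed)
    d = spec.divergence
    bg_a = np.asarray(spec.background_a, dtype=float)
    bg_b_target = np.asarray(spec.background_b, dtype=float)
    bg_b = (1.0 - d) * bg_a + d * bg_b_target
    bg_b = bg_b / bg_b.sum()
    pos_ds, pos_prov = _generate_class(
        "positive", "pos", spec.n_per_class, spec.length_range, bg_a,
        [(1.0, spec.motifs_a)], rng,
    )
    # class B uses its own motif set with probability d, class A's otherwise
    neg_ds, neg_prov = _generate_class(
        "negative", "neg", spec.n_per_class, spec.length_range, bg_b,
        [(1.0 - d, spec.motifs_a), (d, spec.motifs_b)], rng,
    )
    prov = pd.DataFrame(pos_prov + neg_prov)
    return pos_ds, neg_ds, prov


def generate_dataset(spec: SyntheticSpec) -> tuple[LabelledDataset, LabelledDataset]:
    """Generate the positive and negative class datasets for `spec`."""
    pos, neg, _ = generate_dataset_with_provenance(spec)
    return pos, neg


def write_synthetic(spec: SyntheticSpec, out_dir: str | os.PathLike) -> tuple[Path, Path, Path]:
    """Write both classes as FASTA plus a provenance sidecar (TSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pos, neg, prov = generate_dataset_with_provenance(spec)
    pos_path, neg_path = out / "positive.fasta", out / "negative.fasta"
    sidecar = out / "provenance.tsv"
    write_fasta(pos.records, pos_path)
    write_fasta(neg.records, neg_path)
    prov.to_csv(sidecar, sep="\t", index=False)
    return pos_path, neg_path, sidecar


def empirical_composition(dataset: LabelledDataset) -> np.ndarray:
    """Pooled single-nucleotide frequencies over all sequences (A, C, G, U)."""
    if not dataset.records:
        raise ValueError("dataset must be non-empty")
    counts = np.zeros(4)
    idx = {c: i for i, c in enumerate(ALPHABET)}
    for rec in dataset.records:
        for c in rec.residues:
            i = idx.get(c)
            if i is not None:
                counts[i] += 1
    return counts / counts.sum()


def disjoint_motif_spec(
    n_per_class: int = 300,
    divergence: float = 1.0,
    motif_len: int = 15,
    occurrence_prob: float = 0.9,
    mutation_rate: float = 0.05,
    seed: int = 0,
) -> SyntheticSpec:
    """Convenience spec with one disjoint planted motif per class.

    The two consensi share no k-mers longer than 2 nt (A/C-rich vs G/U-rich
    alternations), so at full divergence the classes are separable both by
    motif scores and by k-mer composition.
    """
    motif_a = ("ACGUA" * ((motif_len // 5) + 1))[:motif_len]
    motif_b = ("GAUCC" * ((motif_len // 5) + 1))[:motif_len]
    return SyntheticSpec(
        n_per_class=n_per_class,
        motifs_a=(PlantedMotif(motif_a, occurrence_prob, mutation_rate),),
        motifs_b=(PlantedMotif(motif_b, occurrence_prob, mutation_rate),),
        divergence=divergence,
        seed=seed,
    )
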