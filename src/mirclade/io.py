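"""Reading, normalising and assembling labelled hairpin sequence datasets.

Sequences are handled as RNA: input may be DNA or RNA, any case; on read,
residues are uppercased and T is mapped to U. Records containing symbols
outside {A,C,G,U} (e.g. N) are retained but flagged (`SequenceRecord.is_clean`
is False); downstream feature code treats ambiguous positions as non-matching.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align

ALPHABET = ("A", "C", "G", "U")
_ALPHABET_SET = frozenset(ALPHABET)


class FastaParseError(ValueError):
    """Raised for structurally invalid FASTA input (names the offending line)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One hairpin sequence with identifier and species tag."""

    id: str
    residues: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: residues must be non-empty")

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def is_clean(self) -> bool:
        """True if every residue is one of A/C/G/U."""
        return all(c in _ALPHABET_SET for c in self.residues)


@dataclass(frozen=True)
class LabelledDataset:
    """An ordered collection of records under one class label."""

    records: tuple[SequenceRecord, ...]
    label: str
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids in dataset {self.label!r}: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def sequences(self) -> list[str]:
        return [r.residues for r in self.records]


def normalize_residues(raw: str) -> str:
    """Uppercase and map T to U."""
    return raw.upper().replace("T", "U")


def read_fasta(path: str | os.PathLike, species: str | None = None) -> list[SequenceRecord]:
    """Read a FASTA file into records, in file order.

    The header token before the first whitespace becomes the record id.
    Residues are uppercased with T mapped to U.  Raises
    :class:`FastaParseError` for text before the first header, an empty
    sequence, an empty header, or a duplicated id — naming the line.
    """
    path = Path(path)
    if species is None:
        species = path.stem
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        assert header is not None
        seq = normalize_residues("".join(chunks))
        if not seq:
            raise FastaParseError(
                f"{path}: entry {header!r} at line {header_line} has an empty sequence"
            )
        if header in seen:
            raise FastaParseError(
                f"{path}: duplicate record id {header!r} at line {header_line}"
            )
        seen.add(header)
        records.append(SequenceRecord(id=header, residues=seq, species=species))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FastaParseError(f"{path}: empty header at line {lineno}")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}: sequence data before first '>' header at line {lineno}"
                    )
                chunks.append(line)
    if header is None:
        raise FastaParseError(f"{path}: no FASTA entries found")
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike, width: int = 60) -> None:
    """Write records as FASTA (U alphabet, wrapped at `width` columns)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.residues[i : i + width] + "\n")


# Global (Needleman-Wunsch) aligner used for identity when sequences differ.
# Scores: standard match/mismatch/gap scheme; identity is counted from the
# optimal alignment as identities / alignment length.
_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=2,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-0.5,
)


def global_identity(a: str, b: str) -> float:
    """Pairwise identity: matches / alignment length of a global alignment.

    Identical strings need no alignment and return 1.0 exactly.
    """
    if a == b:
        return 1.0
    counts = _ALIGNER.align(a, b)[0].counts()
    aln_len = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / aln_len


def filter_similar(
    records: Sequence[SequenceRecord], identity_threshold: float = 1.0
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Greedy similarity filtering in input order.

    A record is removed if its global pairwise identity with any previously
    retained record is >= `identity_threshold`.  At threshold 1.0 this removes
    exact duplicates only.  Returns the retained records plus a removal report
    with columns removed_id, retained_id, identity.
    """
    if not records:
        raise ValueError("filter_similar requires a non-empty record collection")
    if not (0.0 < identity_threshold <= 1.0):
        raise ValueError(
            f"identity_threshold must be in (0, 1], got {identity_threshold}"
        )
    retained: list[SequenceRecord] = []
    removed: list[dict] = []
    exact_only = identity_threshold >= 1.0
    seen_seq: dict[str, str] = {}
    for rec in records:
        trigger = None
        identity = 0.0
        if exact_only:
            if rec.residues in seen_seq:
                trigger, identity = seen_seq[rec.residues], 1.0
        else:
            for kept in retained:
                ident = global_identity(rec.residues, kept.residues)
                if ident >= identity_threshold:
                    trigger, identity = kept.id, ident
                    break
        if trigger is None:
            retained.append(rec)
            if exact_only:
                seen_seq.setdefault(rec.residues, rec.id)
        else:
            removed.append(
                {"removed_id": rec.id, "retained_id": trigger, "identity": identity}
            )
    report = pd.DataFrame(removed, columns=["removed_id", "retained_id", "identity"])
    return retained, report


def assemble_group(
    paths: Sequence[str | os.PathLike],
    label: str,
    identity_threshold: float = 1.0,
    species: Sequence[str] | None = None,
    exclude_species: Sequence[str] = (),
) -> LabelledDataset:
    """Build one labelled dataset from per-species FASTA files.

    Similarity filtering is applied within each species file before the files
    are concatenated.  Species listed in `exclude_species` are dropped (used
    e.g. to remove a target species from its containing clade so the two
    classes stay disjoint).  Id collisions across files are an error.
    """
    if not paths:
        raise ValueError("assemble_group requires at least one path")
    if species is not None and len(species) != len(paths):
        raise ValueError("species list must match paths length")
    excluded = set(exclude_species)
    all_records: list[SequenceRecord] = []
    seen: dict[str, str] = {}
    collisions: list[str] = []
    for i, path in enumerate(paths):
        sp = species[i] if species is not None else None
        recs = read_fasta(path, species=sp)
        if recs and recs[0].species in excluded:
            continue
        kept, _ = filter_similar(recs, identity_threshold)
        for rec in kept:
            if rec.id in seen:
                collisions.append(rec.id)
            else:
                seen[rec.id] = str(path)
                all_records.append(rec)
    if collisions:
        raise ValueError(
            f"id collision across species files for label {label!r}: {sorted(set(collisions))}"
        )
    return LabelledDataset(
        records=tuple(all_records), label=label, provenance=tuple(str(p) for p in paths)
    )
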