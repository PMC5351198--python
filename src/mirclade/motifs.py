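"""Motif profiles: MEME minimal format I/O, profile scoring and discovery.

A motif is a position-frequency matrix (width x 4 over A,C,G,U).  A sequence
is scored against a profile by sliding one along the other and, at each
offset, summing the profile frequencies of the matching nucleotides; the
maximum over offsets is the motif feature value.  When the profile is longer
than the sequence, the sequence is shifted fully inside the profile instead.
Scores are raw frequency sums in [0, min(width, length)] — no normalisation.

`discover_motifs_builtin` is a deliberately simple greedy word-seeded
discoverer (NOT a MEME re-implementation): it seeds on the most
over-represented exact word, aligns each sequence's best-matching window,
extends the alignment while the flanking columns stay informative, and masks
strong occurrences before searching for the next motif.  External MEME can be
bridged through :func:`run_meme_external` when the executable is available.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .io import ALPHABET, LabelledDataset, SequenceRecord, write_fasta

_IDX = {c: i for i, c in enumerate(ALPHABET)}
_ROW_SUM_TOL = 1e-3


class MemeParseError(ValueError):
    """Raised for malformed MEME minimal motif text."""


class MemeNotFoundError(RuntimeError):
    """Raised when the external MEME executable cannot be located."""


@dataclass
class MotifProfile:
    """A width x 4 position-frequency matrix over (A, C, G, U)."""

    id: str
    matrix: np.ndarray
    source_class: str = ""
    nsites: int | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 1:
            raise ValueError(f"motif {self.id!r}: matrix must be (width >= 1) x 4")
        if np.any(self.matrix < 0) or np.any(self.matrix > 1):
            raise ValueError(f"motif {self.id!r}: entries must lie in [0, 1]")
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > _ROW_SUM_TOL):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"motif {self.id!r}: row {bad} sums to {sums[bad]:.6f}, expected 1"
            )

    @property
    def width(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits (2 + sum p log2 p)."""
        p = np.clip(self.matrix, 1e-12, 1.0)
        return 2.0 + (p * np.log2(p)).sum(axis=1)


# ---------------------------------------------------------------------------
# MEME minimal motif format


def parse_meme_minimal(text: str) -> list[MotifProfile]:
    """Parse MEME minimal motif format into profiles, order preserved.

    Accepts RNA (ACGU) or DNA (ACGT) alphabets; a T column is treated as U.
    """
    lines = text.splitlines()
    if not any(line.strip().lower().startswith("meme version") for line in lines):
        raise MemeParseError("missing 'MEME version' line")
    perm = None  # column permutation onto (A, C, G, U)
    for line in lines:
        if line.strip().upper().startswith("ALPHABET="):
            letters = line.split("=", 1)[1].split()
            letters = list("".join(letters).upper().replace("T", "U"))
            if sorted(letters) != sorted("ACGU"):
                raise MemeParseError(f"unsupported alphabet {letters!r}")
            perm = [letters.index(c) for c in ALPHABET]
    profiles: list[MotifProfile] = []
    i = 0
    while i < len(lines):
        tokens = lines[i].split()
        if tokens and tokens[0] == "MOTIF":
            motif_id = tokens[1] if len(tokens) > 1 else f"motif_{len(profiles) + 1}"
            i += 1
            # seek the letter-probability matrix header
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix:"
            ):
                if lines[i].split() and lines[i].split()[0] == "MOTIF":
                    raise MemeParseError(f"motif {motif_id!r}: no letter-probability matrix")
                i += 1
            if i >= len(lines):
                raise MemeParseError(f"motif {motif_id!r}: no letter-probability matrix")
            fields = dict(
                zip(
                    lines[i].replace("letter-probability matrix:", "").split()[::2],
                    lines[i].replace("letter-probability matrix:", "").split()[1::2],
                )
            )
            alength = int(fields.get("alength=", 4))
            if alength != 4:
                raise MemeParseError(f"motif {motif_id!r}: alength {alength} != 4")
            if "w=" not in fields:
                raise MemeParseError(f"motif {motif_id!r}: missing w= field")
            width = int(fields["w="])
            nsites = int(float(fields["nsites="])) if "nsites=" in fields else None
            i += 1
            rows: list[list[float]] = []
            while i < len(lines) and len(rows) < width:
                stripped = lines[i].strip()
                if not stripped:
                    break
                parts = stripped.split()
                try:
                    row = [float(x) for x in parts]
                except ValueError:
                    break
                if len(row) != 4:
                    raise MemeParseError(
                        f"motif {motif_id!r}: row {len(rows)} has {len(row)} values, expected 4"
                    )
                rows.append(row)
                i += 1
            if len(rows) != width:
                raise MemeParseError(
                    f"motif {motif_id!r}: declared w={width} but found {len(rows)} rows"
                )
            matrix = np.array(rows)
            if perm is not None:
                matrix = matrix[:, perm]
            try:
                profiles.append(MotifProfile(id=motif_id, matrix=matrix, nsites=nsites))
            except ValueError as exc:
                raise MemeParseError(str(exc)) from exc
        else:
            i += 1
    return profiles


def write_meme_minimal(profiles: Sequence[MotifProfile], path: str | None = None) -> str:
    """Serialise profiles in MEME minimal motif format (RNA alphabet)."""
    out = ["MEME version 4", "", "ALPHABET= ACGU", "", "strands: +", ""]
    out += ["Background letter frequencies", "A 0.25 C 0.25 G 0.25 U 0.25", ""]
    for prof in profiles:
        out.append(f"MOTIF {prof.id}")
        nsites = prof.nsites if prof.nsites is not None else 20
        out.append(
            f"letter-probability matrix: alength= 4 w= {prof.width} nsites= {nsites} E= 0"
        )
        for row in prof.matrix:
            out.append(" " + " ".join(f"{x:.6f}" for x in row))
        out.append("")
    text = "\n".join(out)
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Scoring


def _seq_indices(seq: str) -> np.ndarray:
    """Map residues to 0..3, ambiguous symbols to -1."""
    return np.array([_IDX.get(c, -1) for c in seq], dtype=np.int64)


def _offset_scores(matrix: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Score at every offset; handles both profile-in-sequence and
    sequence-in-profile orientations.  Ambiguous residues contribute 0."""
    w = matrix.shape[0]
    length = idx.shape[0]
    if w <= length:
        windows = sliding_window_view(idx, w)  # (L-w+1, w)
        safe = np.where(windows < 0, 0, windows)
        contrib = matrix[np.arange(w)[None, :], safe]
        contrib = np.where(windows < 0, 0.0, contrib)
        return contrib.sum(axis=1)
    # profile longer than the sequence: shift the sequence inside the profile
    safe = np.where(idx < 0, 0, idx)
    lookup = matrix[:, safe]  # (w, L); lookup[r, i] = matrix[r, idx[i]]
    lookup = np.where(idx[None, :] < 0, 0.0, lookup)
    n_offsets = w - length + 1
    scores = np.empty(n_offsets)
    for o in range(n_offsets):
        scores[o] = np.trace(lookup, offset=-o)
    return scores


def score_motif(profile: MotifProfile, record: SequenceRecord | str) -> float:
    """Best shift-and-sum score of `record` against `profile`.

    The profile is slid along the sequence (or the sequence inside the
    profile, when the profile is longer); each offset scores the sum of
    profile frequencies at the matching nucleotides; the maximum is returned.
    """
    seq = getattr(record, "residues", record)
    if len(seq) < 1:
        raise ValueError("sequence must have length >= 1")
    return float(_offset_scores(profile.matrix, _seq_indices(seq)).max())


def score_motif_bank(
    profiles: Sequence[MotifProfile],
    dataset: LabelledDataset | Sequence[SequenceRecord],
) -> pd.DataFrame:
    """Score every record against every profile.

    Columns are named `<source_class>:<motif id>`; values are raw
    :func:`score_motif` scores.
    """
    if not profiles:
        raise ValueError("score_motif_bank requires at least one profile")
    records = dataset.records if isinstance(dataset, LabelledDataset) else list(dataset)
    columns = [f"{p.source_class}:{p.id}" for p in profiles]
    ids = [r.id for r in records]
    values = np.empty((len(records), len(profiles)))
    indices = [_seq_indices(r.residues) for r in records]
    for j, prof in enumerate(profiles):
        for i, idx in enumerate(indices):
            values[i, j] = _offset_scores(prof.matrix, idx).max()
    return pd.DataFrame(values, index=pd.Index(ids, name="example_id"), columns=columns)


# ---------------------------------------------------------------------------
# Built-in discovery (greedy word-seeded stand-in, not MEME)


def _background(seqs: Sequence[str]) -> np.ndarray:
    counts = np.ones(4)  # pseudocount avoids zero background
    for s in seqs:
        for c in s:
            i = _IDX.get(c)
            if i is not None:
                counts[i] += 1
    return counts / counts.sum()


def _count_words(seqs: Sequence[str], w: int) -> tuple[np.ndarray, np.ndarray]:
    """Count clean w-mers across sequences; returns (codes, counts) where a
    code is the base-4 encoding of the word (lexicographic order preserved)."""
    all_codes = []
    powers = 4 ** np.arange(w - 1, -1, -1, dtype=np.int64)
    for s in seqs:
        idx = _seq_indices(s)
        if idx.shape[0] < w:
            continue
        windows = sliding_window_view(idx, w)
        valid = (windows >= 0).all(axis=1)
        if valid.any():
            all_codes.append(windows[valid] @ powers)
    if not all_codes:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(all_codes), return_counts=True)


def _decode(code: int, w: int) -> str:
    letters = []
    for _ in range(w):
        letters.append(ALPHABET[code % 4])
        code //= 4
    return "".join(reversed(letters))


def _column_counts(seqs: Sequence[str], windows: list[tuple[int, int]], w: int) -> np.ndarray:
    """Per-column nucleotide counts over aligned windows, +1 pseudocount."""
    counts = np.ones((w, 4))
    for si, off in windows:
        for i, c in enumerate(seqs[si][off : off + w]):
            j = _IDX.get(c)
            if j is not None:
                counts[i, j] += 1
    return counts


def _mean_ic(counts: np.ndarray) -> float:
    p = counts / counts.sum(axis=1, keepdims=True)
    return float((2.0 + (p * np.log2(p)).sum(axis=1)).mean())


def discover_motifs_builtin(
    dataset: LabelledDataset,
    n_motifs: int = 100,
    minw: int = 11,
    maxw: int = 50,
    seed: int = 0,
    ext_ic_threshold: float = 0.3,
    mask_fraction: float = 0.8,
) -> list[MotifProfile]:
    """Greedy word-seeded motif discovery (deterministic; `seed` is accepted
    for interface symmetry with stochastic discoverers but unused).

    Per motif: (1) seed on the word of length `minw` most over-represented
    relative to the 0-order background (ties broken lexicographically);
    (2) align each sequence's best-matching window against the one-hot seed;
    (3) extend the alignment symmetrically up to `maxw` while the newly added
    flanking columns average >= `ext_ic_threshold` bits of information;
    (4) build the profile with add-one pseudocounts, then mask occurrences
    scoring >= `mask_fraction` * width (and all exact seed-word occurrences)
    before the next round.
    """
    if len(dataset.records) < 2:
        raise ValueError("motif discovery requires at least 2 sequences")
    if not (1 <= minw <= maxw):
        raise ValueError(f"require 1 <= minw <= maxw, got minw={minw} maxw={maxw}")
    work = [r.residues for r in dataset.records]
    bg = _background(work)
    log_bg = np.log(bg)
    profiles: list[MotifProfile] = []
    for m in range(n_motifs):
        codes, counts = _count_words(work, minw)
        if codes.size == 0:
            break
        # over-representation = count / expected; expected proportional to
        # prod(background) over the word's letters
        digits = np.empty((codes.size, minw), dtype=np.int64)
        rem = codes.copy()
        for pos in range(minw - 1, -1, -1):
            digits[:, pos] = rem % 4
            rem //= 4
        log_ratio = np.log(counts) - log_bg[digits].sum(axis=1)
        best = np.flatnonzero(log_ratio >= log_ratio.max() - 1e-12)
        seed_code = int(codes[best].min())  # lexicographically smallest tie
        seed_word = _decode(seed_code, minw)

        seed_matrix = np.full((minw, 4), 1e-9)
        for i, c in enumerate(seed_word):
            seed_matrix[i, _IDX[c]] = 1.0
        seed_matrix /= seed_matrix.sum(axis=1, keepdims=True)

        windows: list[tuple[int, int]] = []
        for si, s in enumerate(work):
            if len(s) < minw:
                continue
            scores = _offset_scores(seed_matrix, _seq_indices(s))
            windows.append((si, int(scores.argmax())))
        if not windows:
            break

        # symmetric extension while the new flanking columns stay informative
        cur_w = minw
        while cur_w + 2 <= maxw:
            cand = [
                (si, off - 1)
                for si, off in windows
                if off - 1 >= 0 and off - 1 + cur_w + 2 <= len(work[si])
            ]
            if len(cand) < max(2, len(windows) // 2):
                break
            flank_counts = np.ones((2, 4))
            for si, off in cand:
                for col, pos in ((0, off), (1, off + cur_w + 1)):
                    j = _IDX.get(work[si][pos])
                    if j is not None:
                        flank_counts[col, j] += 1
            if _mean_ic(flank_counts) < ext_ic_threshold:
                break
            windows = cand
            cur_w += 2

        col_counts = _column_counts(work, windows, cur_w)
        matrix = col_counts / col_counts.sum(axis=1, keepdims=True)
        profile = MotifProfile(
            id=f"m{m + 1}",
            matrix=matrix,
            source_class=dataset.label,
            nsites=len(windows),
        )
        profiles.append(profile)

        # mask strong occurrences (and all exact seed words) so the next
        # round finds something new
        threshold = mask_fraction * cur_w
        for si, s in enumerate(work):
            masked = list(s)
            if len(s) >= cur_w:
                scores = _offset_scores(matrix, _seq_indices(s))
                for off in np.flatnonzero(scores >= threshold):
                    for p in range(off, off + cur_w):
                        masked[p] = "N"
            start = s.find(seed_word)
            while start != -1:
                for p in range(start, start + minw):
                    masked[p] = "N"
                start = s.find(seed_word, start + 1)
            work[si] = "".join(masked)
    return profiles


# ---------------------------------------------------------------------------
# External MEME bridge (optional)


def run_meme_external(
    dataset: LabelledDataset,
    meme_executable: str = "meme",
    n_motifs: int = 100,
    minw: int = 11,
    maxw: int = 50,
) -> list[MotifProfile]:
    """Run the external MEME executable on the dataset and parse its output.

    Requires MEME to be installed separately.  If the executable is missing a
    :class:`MemeNotFoundError` is raised advising
    :func:`discover_motifs_builtin` instead.
    """
    exe = shutil.which(meme_executable) or (
        meme_executable if Path(meme_executable).is_file() else None
    )
    if exe is None:
        raise MemeNotFoundError(
            f"MEME executable {meme_executable!r} not found; use "
            "discover_motifs_builtin for the built-in discoverer"
        )
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "input.fasta"
        write_fasta(dataset.records, fasta)
        cmd = [
            exe,
            str(fasta),
            "-rna",
            "-text",
            "-nmotifs",
            str(n_motifs),
            "-minw",
            str(minw),
            "-maxw",
            str(maxw),
        ]
        result = subprocess.run(cmd, capture_output=True, text=True)
        if result.returncode != 0:
            raise RuntimeError(
                f"MEME exited with status {result.returncode}:\n{result.stderr}"
            )
        profiles = parse_meme_minimal(result.stdout)
    for prof in profiles:
        prof.source_class = dataset.label
    return profiles
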