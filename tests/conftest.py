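import numpy as np
import pytest

from mirclade import LabelledDataset, SequenceRecord

ALPHABET = "ACGU"


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(ALPHABET), size=length))


def make_dataset(seqs, label="positive", prefix="s") -> LabelledDataset:
    records = tuple(
        SequenceRecord(id=f"{prefix}{i}", residues=s, species=label)
        for i, s in enumerate(seqs)
    )
    return LabelledDataset(records=records, label=label)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def fasta_writer(tmp_path):
    def write(name, entries):
        path = tmp_path / name
        with open(path, "w") as fh:
            for header, seq in entries:
                fh.write(f">{header}\n{seq}\n")
        return path

    return write
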