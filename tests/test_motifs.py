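"""Motif profile parsing, scoring and built-in discovery."""

import os
import stat

import numpy as np
import pytest

from mirclade import (
    MemeNotFoundError,
    MemeParseError,
    MotifProfile,
    SequenceRecord,
    discover_motifs_builtin,
    parse_meme_minimal,
    run_meme_external,
    score_motif,
    score_motif_bank,
    write_meme_minimal,
)

from conftest import make_dataset, random_sequence

MINIMAL_ONE_HOT = """MEME version 4

ALPHABET= ACGU

MOTIF probe
letter-probability matrix: alength= 4 w= 3 nsites= 10 E= 0
 1.0 0.0 0.0 0.0
 0.0 1.0 0.0 0.0
 0.0 0.0 1.0 0.0
"""


def random_profile(rng, width, motif_id="m"):
    matrix = rng.dirichlet(np.ones(4), size=width)
    return MotifProfile(id=motif_id, matrix=matrix)


class TestMemeFormat:
    def test_parse_one_hot_motif(self):
        profiles = parse_meme_minimal(MINIMAL_ONE_HOT)
        assert len(profiles) == 1
        assert profiles[0].width == 3
        assert profiles[0].consensus == "ACG"
        assert profiles[0].nsites == 10

    def test_declared_width_mismatch_is_an_error(self):
        text = MINIMAL_ONE_HOT.replace("w= 3", "w= 4")
        with pytest.raises(MemeParseError, match="probe"):
            parse_meme_minimal(text)

    def test_row_not_summing_to_one_is_an_error(self):
        text = MINIMAL_ONE_HOT.replace(" 1.0 0.0 0.0 0.0", " 0.8 0.0 0.0 0.0")
        with pytest.raises(MemeParseError, match="probe"):
            parse_meme_minimal(text)

    def test_wrong_alength_is_an_error(self):
        text = MINIMAL_ONE_HOT.replace("alength= 4", "alength= 20")
        with pytest.raises(MemeParseError, match="alength"):
            parse_meme_minimal(text)

    def test_missing_version_line_is_an_error(self):
        with pytest.raises(MemeParseError, match="version"):
            parse_meme_minimal("MOTIF x\n")

    def test_dna_alphabet_t_column_maps_to_u(self):
        text = MINIMAL_ONE_HOT.replace("ALPHABET= ACGU", "ALPHABET= ACGT")
        text = text.replace(" 0.0 0.0 1.0 0.0", " 0.0 0.0 0.0 1.0")
        prof = parse_meme_minimal(text)[0]
        assert prof.consensus == "ACU"

    def test_write_parse_round_trip(self, rng):
        profiles = [random_profile(rng, int(w), f"m{i}") for i, w in enumerate([3, 7, 11, 20, 5])]
        text = write_meme_minimal(profiles)
        back = parse_meme_minimal(text)
        assert [p.id for p in back] == [p.id for p in profiles]
        for orig, rt in zip(profiles, back):
            np.testing.assert_allclose(orig.matrix, rt.matrix, atol=1e-6)

    def test_profile_invariants_enforced(self):
        with pytest.raises(ValueError, match="sums"):
            MotifProfile(id="bad", matrix=np.full((3, 4), 0.3))


class TestScoring:
    def test_perfect_consensus_scores_width(self, rng):
        matrix = np.zeros((5, 4))
        for i, c in enumerate("ACGUA"):
            matrix[i, "ACGU".index(c)] = 1.0
        prof = MotifProfile(id="hot", matrix=matrix)
        seq = random_sequence(rng, 10) + "ACGUA" + random_sequence(rng, 10)
        assert score_motif(prof, seq) == pytest.approx(5.0)

    def test_uniform_profile_scores_quarter_width(self, rng):
        prof = MotifProfile(id="uni", matrix=np.full((4, 4), 0.25))
        assert score_motif(prof, random_sequence(rng, 10)) == pytest.approx(1.0)

    def test_matches_brute_force_over_all_offsets(self, rng):
        for trial in range(200):
            w = int(rng.integers(2, 12))
            L = int(rng.integers(1, 25))
            prof = random_profile(rng, w, f"t{trial}")
            seq = random_sequence(rng, L)
            # brute force both orientations
            if w <= L:
                expected = max(
                    sum(prof.matrix[i, "ACGU".index(seq[o + i])] for i in range(w))
                    for o in range(L - w + 1)
                )
            else:
                expected = max(
                    sum(prof.matrix[o + i, "ACGU".index(seq[i])] for i in range(L))
                    for o in range(w - L + 1)
                )
            assert score_motif(prof, seq) == pytest.approx(expected)

    def test_score_bounded_by_min_width_length(self, rng):
        for _ in range(50):
            prof = random_profile(rng, int(rng.integers(2, 15)))
            seq = random_sequence(rng, int(rng.integers(1, 30)))
            assert 0.0 <= score_motif(prof, seq) <= min(prof.width, len(seq)) + 1e-9

    def test_ambiguous_residues_contribute_zero(self):
        prof = MotifProfile(id="uni", matrix=np.full((2, 4), 0.25))
        assert score_motif(prof, "NN") == 0.0
        assert score_motif(prof, "AN") == pytest.approx(0.25)

    def test_score_monotone_under_appending(self, rng):
        for _ in range(30):
            prof = random_profile(rng, 6)
            seq = random_sequence(rng, 12)
            longer = seq + random_sequence(rng, 8)
            assert score_motif(prof, longer) >= score_motif(prof, seq) - 1e-12

    def test_bank_matches_elementwise_scores(self, rng):
        profiles = [random_profile(rng, 4, "p1"), random_profile(rng, 6, "p2")]
        for p in profiles:
            p.source_class = "positive"
        ds = make_dataset([random_sequence(rng, 20) for _ in range(3)])
        block = score_motif_bank(profiles, ds)
        assert block.shape == (3, 2)
        assert list(block.columns) == ["positive:p1", "positive:p2"]
        for j, prof in enumerate(profiles):
            for i, rec in enumerate(ds.records):
                assert block.iloc[i, j] == pytest.approx(score_motif(prof, rec))

    def test_single_class_bank_has_one_column_per_profile(self, rng):
        profiles = [random_profile(rng, 4, f"p{i}") for i in range(100)]
        ds = make_dataset([random_sequence(rng, 25)])
        assert score_motif_bank(profiles, ds).shape == (1, 100)


class TestDiscovery:
    def test_recovers_exact_planted_word(self, rng):
        word = "ACGUACGUACG"
        seqs = []
        for _ in range(50):
            s = list(random_sequence(rng, 80))
            pos = int(rng.integers(0, 80 - len(word) + 1))
            s[pos : pos + len(word)] = list(word)
            seqs.append("".join(s))
        profiles = discover_motifs_builtin(make_dataset(seqs), n_motifs=1, minw=11, maxw=50)
        assert profiles[0].consensus == word

    def test_identical_sequences_saturate_column_information(self):
        # a degenerate alignment reaches the pseudocount-limited IC maximum,
        # which tends to 2 bits/column as the number of sequences grows
        n = 30
        ds = make_dataset(["ACGUACGUACGUACGUACGU"] * n)
        prof = discover_motifs_builtin(ds, n_motifs=1, minw=11, maxw=20)[0]
        p, q = (n + 1) / (n + 4), 1 / (n + 4)
        ic_max = 2 + p * np.log2(p) + 3 * q * np.log2(q)
        np.testing.assert_allclose(prof.information_content(), ic_max, atol=1e-9)

    def test_deterministic_given_seed(self, rng):
        ds = make_dataset([random_sequence(rng, 70) for _ in range(20)])
        a = discover_motifs_builtin(ds, n_motifs=3, minw=8, maxw=20, seed=7)
        b = discover_motifs_builtin(ds, n_motifs=3, minw=8, maxw=20, seed=7)
        assert len(a) == len(b) == 3
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.matrix, pb.matrix)

    def test_too_small_dataset_is_an_error(self):
        ds = make_dataset(["ACGUACGUACGU"])
        with pytest.raises(ValueError, match="at least 2"):
            discover_motifs_builtin(ds, n_motifs=1)

    def test_profiles_tagged_with_source_class(self, rng):
        ds = make_dataset([random_sequence(rng, 60) for _ in range(10)], label="negative")
        profs = discover_motifs_builtin(ds, n_motifs=2, minw=6, maxw=12)
        assert all(p.source_class == "negative" for p in profs)

    def test_planted_motif_recovery_rate(self):
        # occurrence probability 1.0, mutation rate 0.05, 20 seeded trials:
        # consensus within Hamming distance 1 in at least 90% of trials
        word = "ACGUACGUACG"
        hits = 0
        for trial in range(20):
            rng = np.random.default_rng(1000 + trial)
            seqs = []
            for _ in range(50):
                s = list(random_sequence(rng, 90))
                inst = [
                    c if rng.random() >= 0.05 else rng.choice([x for x in "ACGU" if x != c])
                    for c in word
                ]
                pos = int(rng.integers(0, 90 - len(word) + 1))
                s[pos : pos + len(word)] = inst
                seqs.append("".join(s))
            prof = discover_motifs_builtin(make_dataset(seqs), n_motifs=1, minw=11, maxw=50)[0]
            consensus = prof.consensus
            if len(consensus) == len(word):
                hamming = sum(a != b for a, b in zip(consensus, word))
                hits += hamming <= 1
        assert hits >= 18


class TestExternalMeme:
    def test_missing_executable_advises_builtin(self, rng):
        ds = make_dataset([random_sequence(rng, 40) for _ in range(3)])
        with pytest.raises(MemeNotFoundError, match="builtin"):
            run_meme_external(ds, "definitely-not-meme-anywhere")

    def test_stub_executable_output_is_parsed(self, tmp_path, rng):
        fixture = write_meme_minimal(
            [random_profile(rng, w, f"fx{i}") for i, w in enumerate([4, 6, 8])]
        )
        fixture_path = tmp_path / "fixture.meme"
        fixture_path.write_text(fixture)
        stub = tmp_path / "fake-meme"
        stub.write_text(f"#!/bin/sh\ncat {fixture_path}\n")
        stub.chmod(stub.stat().st_mode | stat.S_IEXEC)
        ds = make_dataset([random_sequence(rng, 40) for _ in range(3)])
        profiles = run_meme_external(ds, str(stub), n_motifs=3, minw=4, maxw=8)
        assert [p.id for p in profiles] == ["fx0", "fx1", "fx2"]
        assert all(p.source_class == "positive" for p in profiles)

    def test_nonzero_exit_raises_with_log(self, tmp_path, rng):
        stub = tmp_path / "broken-meme"
        stub.write_text("#!/bin/sh\necho boom >&2\nexit 3\n")
        stub.chmod(stub.stat().st_mode | stat.S_IEXEC)
        ds = make_dataset([random_sequence(rng, 40) for _ in range(3)])
        with pytest.raises(RuntimeError, match="boom"):
            run_meme_external(ds, str(stub))
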